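"""Quality filters: stop codons, coverage, block masking, backtranslation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import convscan as cs
from convscan.qc_filters import default_b1, default_b2, mask_blocks


class TestPrematureStops:
    def test_terminal_stop_kept_and_trimmed(self):
        kept, removed = cs.remove_premature_stops(cs.CdsSet([("s1", "ATGAAATAA")]))
        assert kept.ids == ["s1"] and not removed
        from convscan.qc_filters import translate_cds
        assert translate_cds("ATGAAATAA") == "MK"

    def test_internal_stop_removed(self):
        kept, removed = cs.remove_premature_stops(cs.CdsSet([("s1", "ATGTAAAAA")]))
        assert kept.ids == [] and removed[0].reason == "internal_stop"

    def test_batch_matches_per_record_translation(self):
        cds = cs.CdsSet([("s1", "ATGAAATAA"), ("s2", "ATGTGATTT"),
                         ("s3", "ATGCCC")])
        kept, removed = cs.remove_premature_stops(cds)
        assert kept.ids == ["s1", "s3"]
        assert [r.seq_id for r in removed] == ["s2"]

    def test_out_of_frame_removed_with_frame_reason(self):
        kept, removed = cs.remove_premature_stops(cs.CdsSet([("s1", "ATGAA")]))
        assert kept.ids == [] and removed[0].reason == "frame"

    def test_idempotent(self):
        cds = cs.CdsSet([("s1", "ATGAAATAA"), ("s2", "ATGTGATTT")])
        once, _ = cs.remove_premature_stops(cds)
        twice, removed = cs.remove_premature_stops(once)
        assert twice.records == once.records and not removed


class TestCleanAlignment:
    def test_defaults_match_filter_convention(self):
        import inspect
        sig = inspect.signature(cs.clean_alignment)
        assert sig.parameters["min_len"].default == 20
        assert sig.parameters["min_cov"].default == 0.30
        assert sig.parameters["min_taxa"].default == 2

    def test_no_filter_fires_on_clean_alignment(self):
        msa = cs.Msa([(f"s{i}", "MKVLERTANQSWHHGFDDCPAILKRERTK" + "A")
                      for i in range(3)])
        out, removed = cs.clean_alignment(msa)
        assert out.records == msa.records and not removed

    def test_short_and_low_coverage_removed_then_dropped(self):
        n = 100
        seq_full = "K" * n
        seq_19 = "K" * 19 + "-" * (n - 19)         # short: 19 < 20 residues
        seq_25 = "K" * 25 + "-" * (n - 25)         # 25% coverage < 30%
        msa = cs.Msa([("full", seq_full), ("short", seq_19), ("low", seq_25)])
        out, removed = cs.clean_alignment(msa)
        assert out is None  # only one sequence left -> DROPPED
        reasons = {r.seq_id: r.reason for r in removed}
        assert reasons["short"] == "short"
        assert reasons["low"] == "low_coverage"

    def test_survivors_kept_and_allgap_columns_deleted(self):
        msa = cs.Msa([
            ("a", "KKKKKKKKKKKKKKKKKKKKKKKKK-----"),
            ("b", "KKKKKKKKKKKKKKKKKKKKKKKKK-----"),
            ("c", "KKKKK-------------------------"),
        ])
        out, removed = cs.clean_alignment(msa)
        assert out.ids == ["a", "b"]
        assert out.n_columns == 25
        assert out.column_map == list(range(25))

    def test_idempotent(self):
        msa = cs.Msa([
            ("a", "KKKKKKKKKKKKKKKKKKKKKKKKK-----"),
            ("b", "KKKKKKKKKKKKKKKKKKKKKKKKK-----"),
            ("c", "KKKKK-------------------------"),
        ])
        once, _ = cs.clean_alignment(msa)
        twice, removed = cs.clean_alignment(once)
        assert twice.records == once.records and not removed


class TestDropHighMissing:
    def test_boundary_90_removed_89_retained(self):
        seq90 = "-" * 90 + "K" * 10
        seq89 = "-" * 89 + "K" * 11
        full = "K" * 100
        msa = cs.Msa([("m90", seq90), ("m89", seq89), ("full", full)])
        out, removed = cs.drop_high_missing(msa)
        assert [r.seq_id for r in removed] == ["m90"]
        assert sorted(out.ids) == ["full", "m89"]

    def test_exclusive_boundary_flag(self):
        seq90 = "-" * 90 + "K" * 10
        msa = cs.Msa([("m90", seq90), ("full", "K" * 100)])
        out, removed = cs.drop_high_missing(msa, inclusive=False)
        assert not removed and sorted(out.ids) == ["full", "m90"]

    def test_x_counts_as_missing(self):
        msa = cs.Msa([("x", "X" * 45 + "-" * 45 + "K" * 10),
                      ("full", "K" * 100)])
        _, removed = cs.drop_high_missing(msa)
        assert [r.seq_id for r in removed] == ["x"]

    def test_gapless_alignment_unchanged(self):
        msa = cs.Msa([("a", "MKVL"), ("b", "MRVL")])
        out, removed = cs.drop_high_missing(msa)
        assert out.records == msa.records and not removed


class TestMaskBlocks:
    def test_identical_sequences_fully_retained(self):
        msa = cs.Msa([(f"s{i}", "MKVLERTANQSWHHGFDDCPAILKRETANQ") for i in range(6)])
        out = mask_blocks(msa)
        assert out.n_columns == 30
        assert out.column_map == list(range(30))

    def test_all_distinct_columns_fully_rejected(self):
        # 8 sequences, every column has 8 different residues
        rows = ["ARNDCQEG", "RNDCQEGH", "NDCQEGHI", "DCQEGHIL",
                "CQEGHILK", "QEGHILKM", "EGHILKMF", "GHILKMFP"]
        msa = cs.Msa([(f"s{i}", rows[i] * 5) for i in range(8)])
        out = mask_blocks(msa)
        assert out.n_columns == 0

    def test_nonconserved_stretch_removed_flanks_kept(self):
        # 8 sequences, 40 columns; columns 18-20 (0-based) all-distinct
        n, length = 8, 40
        distinct = ["ARNDCQEG", "RNDCQEGH", "NDCQEGHI"]
        rows = []
        for i in range(n):
            row = list("K" * length)
            for j, col in enumerate(range(18, 21)):
                row[col] = distinct[j][i]
            rows.append((f"s{i}", "".join(row)))
        out = mask_blocks(cs.Msa(rows))
        kept = set(out.column_map)
        assert kept == set(range(18)) | set(range(21, 40))

    def test_short_block_below_b4_dropped(self):
        # conserved islands of 3 columns between rejected stretches vanish
        n = 8
        distinct = ["ARNDCQEG", "RNDCQEGH", "NDCQEGHI", "DCQEGHIL"]
        cols = []
        for pattern in (["K"] * 3 + [None] * 4) * 3:
            cols.append(pattern)
        rows = []
        for i in range(n):
            chars = []
            d = 0
            for pattern in cols:
                if pattern is None:
                    chars.append(distinct[d % 4][i])
                    d += 1
                else:
                    chars.append(pattern)
            rows.append((f"s{i}", "".join(chars)))
        out = mask_blocks(cs.Msa(rows))
        assert out.n_columns == 0

    def test_gap_mode_half_disqualifies_gappy_columns(self):
        n = 6
        rows = []
        for i in range(n):
            gappy = "-" if i < 4 else "K"   # 4 of 6 gaps > n/2
            rows.append((f"s{i}", "KKKKKKKK" + gappy * 4 + "KKKKKKKK"))
        out = mask_blocks(cs.Msa(rows))
        assert set(out.column_map) == set(range(8)) | set(range(12, 20))

    def test_b1_b2_dialect_values(self):
        assert default_b1(8) == 7 and default_b2(8) == 7
        assert default_b1(6) == 5 and default_b2(6) == 6
        assert default_b1(9) == 7 and default_b2(9) == 8

    def test_idempotent_and_subsequence(self):
        rng = np.random.default_rng(7)
        alphabet = cs.load_model("LG").alphabet
        for _ in range(10):
            rows = []
            base = rng.choice(list(alphabet), size=30)
            for i in range(6):
                row = base.copy()
                flips = rng.random(30) < 0.3
                row[flips] = rng.choice(list(alphabet), size=flips.sum())
                rows.append((f"s{i}", "".join(row)))
            msa = cs.Msa(rows)
            once = mask_blocks(msa)
            assert all(b > a for a, b in
                       zip(once.column_map, once.column_map[1:]))
            if once.n_columns == 0:
                continue
            twice = mask_blocks(once)
            assert twice.records == once.records
            assert twice.column_map == once.column_map


class TestBacktranslate:
    def test_gap_maps_to_triple_gap(self):
        msa = cs.Msa([("s1", "M-K")])
        out = cs.backtranslate(msa, cs.CdsSet([("s1", "ATGAAA")]))
        assert out.sequence("s1") == "ATG---AAA"

    def test_plain_mapping_and_terminal_stop(self):
        msa = cs.Msa([("s1", "MK")])
        out = cs.backtranslate(msa, cs.CdsSet([("s1", "ATGAAGTAA")]))
        assert out.sequence("s1") == "ATGAAG"

    def test_mismatch_names_record_and_position(self):
        msa = cs.Msa([("s1", "MK")])
        with pytest.raises(cs.ValidationError, match=r"s1.*position 2"):
            cs.backtranslate(msa, cs.CdsSet([("s1", "ATGCCC")]))

    def test_output_length_triples(self):
        msa = cs.Msa([("s1", "M-KV"), ("s2", "MRKV")])
        cds = cs.CdsSet([("s1", "ATGAAAGTT"), ("s2", "ATGCGCAAAGTC")])
        out = cs.backtranslate(msa, cds)
        assert out.n_columns == 3 * msa.n_columns

    def test_commutes_with_column_selection(self):
        msa = cs.Msa([("s1", "M-KVL"), ("s2", "MRKVL")])
        cds = cs.CdsSet([("s1", "ATGAAAGTTCTT"), ("s2", "ATGCGCAAAGTCCTG")])
        keep = [0, 2, 4]
        # CDS trimmed to the codons of residues that survive the selection
        trimmed = []
        for seq_id, row in msa.records:
            nt = cds.sequence(seq_id)
            residue = 0
            kept_codons = []
            for j, aa in enumerate(row):
                if aa == "-":
                    continue
                if j in keep:
                    kept_codons.append(nt[3 * residue:3 * residue + 3])
                residue += 1
            trimmed.append((seq_id, "".join(kept_codons)))
        direct = cs.backtranslate(msa.select_columns(keep),
                                  cs.CdsSet(trimmed))
        full = cs.backtranslate(msa, cds)
        codon_cols = [c for j in keep for c in (3 * j, 3 * j + 1, 3 * j + 2)]
        via_full = full.select_columns(codon_cols)
        assert [(i, s) for i, s in direct.records] == \
            [(i, s) for i, s in via_full.records]


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_filters_never_increase_missing_fraction(seed):
    rng = np.random.default_rng(seed)
    n_seq, n_col = int(rng.integers(3, 7)), int(rng.integers(10, 40))
    rows = []
    for i in range(n_seq):
        chars = rng.choice(list("KRNDE-"), size=n_col,
                           p=[0.15, 0.15, 0.15, 0.15, 0.15, 0.25])
        rows.append((f"s{i}", "".join(chars)))
    msa = cs.Msa(rows)

    def missing_frac(m, sid):
        s = m.sequence(sid)
        return sum(c in "-X" for c in s) / len(s)

    before = {i: missing_frac(msa, i) for i in msa.ids}
    for fn in (lambda m: cs.clean_alignment(m, min_len=2, min_cov=0.05)[0],
               lambda m: cs.drop_high_missing(m)[0]):
        out = fn(msa)
        if out is None:
            continue
        for sid in out.ids:
            assert missing_frac(out, sid) <= before[sid] + 1e-12
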