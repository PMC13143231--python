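"""Sequence- and alignment-level quality control.

Implements the filter cascade applied to each orthogroup before selection and
convergence analyses: premature-stop exclusion for coding sequences, removal
of short / low-coverage sequences (defaults 20 residues, 30% non-gap
coverage, minimum two retained taxa), conserved-block masking with the
Gblocks parameterisation b3=2, b4=5, gap mode "half", removal of sequences
with >=90% missing data, and backtranslation of protein alignments to codon
alignments.

The block masker is a deterministic dialect of the classic conserved-block
filter, not a byte-exact re-implementation: column conservation is defined by
the majority-residue count against thresholds b1 = floor(0.75*n)+1 and
b2 = ceil(0.85*n), and a column with gaps in more than floor(n/2) sequences
is never conserved.  All filters are idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .seqio import GAP, MISSING, CdsSet, Msa, ValidationError


@dataclass
class RemovalRecord:
    """Per-sequence audit entry emitted by every filter stage."""
    seq_id: str
    stage: str
    reason: str


# ---------------------------------------------------------------------------
# Coding-sequence filters
# ---------------------------------------------------------------------------

def translate_cds(nt: str) -> str:
    """Translate an in-frame CDS with the standard code; trims one terminal stop.

    Raises ValidationError when the length is not divisible by 3 or a stop
    codon occurs before the final codon.
    """
    if len(nt) % 3 != 0:
        raise ValidationError("CDS length not divisible by 3")
    aa = str(Seq(nt).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValidationError(f"premature stop at codon {aa.index('*') + 1}")
    return aa


def remove_premature_stops(cds: CdsSet) -> tuple[CdsSet, list[RemovalRecord]]:
    """Drop records whose translation stops before the final codon.

    A single terminal stop codon is permitted (and trimmed at translation
    time).  Records whose length is not a multiple of 3 are removed with
    reason ``frame`` rather than raising.
    """
    kept, removed = [], []
    for seq_id, nt in cds.records:
        if len(nt) % 3 != 0:
            removed.append(RemovalRecord(seq_id, "premature_stop", "frame"))
            continue
        aa = str(Seq(nt).translate(table=1))
        body = aa[:-1] if aa.endswith("*") else aa
        if "*" in body:
            removed.append(RemovalRecord(seq_id, "premature_stop", "internal_stop"))
        else:
            kept.append((seq_id, nt))
    return CdsSet(kept, genetic_code=cds.genetic_code), removed


# ---------------------------------------------------------------------------
# Alignment filters
# ---------------------------------------------------------------------------

def clean_alignment(
    msa: Msa,
    min_len: int = 20,
    min_cov: float = 0.30,
    min_taxa: int = 2,
) -> tuple[Optional[Msa], list[RemovalRecord]]:
    """Remove short and low-coverage sequences; ``None`` means DROPPED.

    A sequence is removed when it has fewer than ``min_len`` non-gap residues
    or when its non-gap coverage is below ``min_cov``.  Columns left all-gap
    are deleted (column_map updated).  If fewer than ``min_taxa`` sequences
    survive, the whole alignment is dropped.
    """
    removed: list[RemovalRecord] = []
    keep: list[str] = []
    n_cols = msa.n_columns
    for seq_id, seq in msa.records:
        non_gap = sum(1 for c in seq if c != GAP)
        if non_gap < min_len:
            removed.append(RemovalRecord(seq_id, "clean_alignment", "short"))
        elif n_cols > 0 and non_gap / n_cols < min_cov:
            removed.append(RemovalRecord(seq_id, "clean_alignment", "low_coverage"))
        else:
            keep.append(seq_id)
    if len(keep) < min_taxa:
        removed.extend(RemovalRecord(i, "clean_alignment", "orthogroup_dropped")
                       for i in keep)
        return None, removed
    out = msa.select_rows(keep).drop_allgap_columns()
    return out, removed


def drop_high_missing(
    msa: Msa,
    max_missing: float = 0.90,
    inclusive: bool = True,
) -> tuple[Optional[Msa], list[RemovalRecord]]:
    """Remove sequences dominated by missing data (gaps or ``X``).

    With the default inclusive boundary a sequence is removed when its
    missing fraction is >= ``max_missing``; set ``inclusive=False`` for a
    strict ``>`` reading.  Returns ``None`` if nothing survives.
    """
    removed, keep = [], []
    n_cols = msa.n_columns
    for seq_id, seq in msa.records:
        frac = sum(1 for c in seq if c in (GAP, MISSING)) / n_cols
        hit = frac >= max_missing if inclusive else frac > max_missing
        if hit:
            removed.append(RemovalRecord(seq_id, "drop_high_missing", "high_missing"))
        else:
            keep.append(seq_id)
    if not keep:
        return None, removed
    return msa.select_rows(keep).drop_allgap_columns(), removed


# ---------------------------------------------------------------------------
# Conserved-block masking
# ---------------------------------------------------------------------------

def default_b1(n_seq: int) -> int:
    return math.floor(n_seq * 0.75) + 1


def default_b2(n_seq: int) -> int:
    return math.ceil(n_seq * 0.85)


def _column_status(column: str, b1: int, b2: int, gap_mode: str) -> str:
    n = len(column)
    gaps = sum(1 for c in column if c == GAP)
    if gap_mode == "none" and gaps > 0:
        return "nonconserved"
    if gap_mode == "half" and gaps > n // 2:
        return "nonconserved"
    residues = [c for c in column if c != GAP]
    if not residues:
        return "nonconserved"
    majority = max(residues.count(r) for r in set(residues))
    if majority >= b2:
        return "highly_conserved"
    if majority >= b1:
        return "conserved"
    return "nonconserved"


def mask_blocks(
    msa: Msa,
    b1: Optional[int] = None,
    b2: Optional[int] = None,
    b3: int = 2,
    b4: int = 5,
    gap_mode: str = "half",
) -> Msa:
    """Retain conserved alignment blocks (Gblocks-style parameters).

    Column classification: majority-residue count >= b2 -> highly conserved,
    >= b1 -> conserved, otherwise nonconserved; a column with gaps in more
    than half the sequences (gap mode "half") is always nonconserved.  Runs
    of more than ``b3`` contiguous nonconserved columns are rejected, the
    remaining segments are trimmed to highly-conserved anchors at both
    flanks, and blocks shorter than ``b4`` are discarded.  May return a
    0-column alignment.
    """
    n = msa.n_sequences
    if n < 2:
        raise ValidationError("block masking needs at least 2 sequences")
    if b1 is None:
        b1 = default_b1(n)
    if b2 is None:
        b2 = default_b2(n)
    b2 = max(b1, b2)
    if gap_mode not in ("half", "none", "all"):
        raise ValidationError(f"unknown gap mode {gap_mode!r}")

    status = [_column_status(msa.column(j), b1, b2, gap_mode)
              for j in range(msa.n_columns)]

    rejected = [False] * len(status)
    j = 0
    while j < len(status):
        if status[j] == "nonconserved":
            k = j
            while k < len(status) and status[k] == "nonconserved":
                k += 1
            if k - j > b3:
                for m in range(j, k):
                    rejected[m] = True
            j = k
        else:
            j += 1

    keep: list[int] = []
    j = 0
    while j < len(status):
        if rejected[j]:
            j += 1
            continue
        k = j
        while k < len(status) and not rejected[k]:
            k += 1
        block = list(range(j, k))
        # trim flanks to highly conserved anchors
        while block and status[block[0]] != "highly_conserved":
            block.pop(0)
        while block and status[block[-1]] != "highly_conserved":
            block.pop()
        if len(block) >= b4:
            keep.extend(block)
        j = k

    return msa.select_columns(keep)


# ---------------------------------------------------------------------------
# Backtranslation
# ---------------------------------------------------------------------------

def backtranslate(protein_msa: Msa, cds: CdsSet) -> Msa:
    """Map each amino-acid column of the alignment onto its source codon.

    Every protein record must have a CDS whose in-frame translation (after
    trimming one terminal stop) equals the ungapped protein; gaps map to
    ``---``.  A mismatch raises, naming the record and the first
    disagreeing amino-acid position (1-based).
    """
    rows = []
    for seq_id, aa_row in protein_msa.records:
        nt = cds.sequence(seq_id)
        if len(nt) % 3 != 0:
            raise ValidationError(f"{seq_id}: CDS length not divisible by 3")
        translated = str(Seq(nt).translate(table=1))
        if translated.endswith("*"):
            translated = translated[:-1]
            nt = nt[:-3]
        ungapped = aa_row.replace(GAP, "")
        if len(translated) != len(ungapped):
            raise ValidationError(
                f"{seq_id}: CDS translates to {len(translated)} aa, "
                f"alignment row has {len(ungapped)}")
        for pos, (a, b) in enumerate(zip(translated, ungapped), start=1):
            if a != b and b != MISSING:
                raise ValidationError(
                    f"{seq_id}: translation mismatch at position {pos} "
                    f"({a!r} vs {b!r})")
        codons = [nt[3 * k:3 * k + 3] for k in range(len(translated))]
        out, k = [], 0
        for c in aa_row:
            if c == GAP:
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        rows.append((seq_id, "".join(out)))
    return Msa(rows)
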