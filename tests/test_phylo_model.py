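"""Substitution models, pruning likelihoods, marginal reconstruction."""

import itertools

import numpy as np
import pytest

import convscan as cs
from convscan.phylo_model import (empirical_frequencies, log_likelihood,
                                  site_log_likelihoods)
from convscan.reference import enumerate_posteriors, enumerate_site_likelihood
from convscan.synthetic_data import default_config, simulate_alignment

from conftest import random_rooted_tree

QUARTET_SHAPES = [
    "((A:{a},B:{b}){s}:{e},(C:{c},D:{d}){s}:{f});",       # balanced
    "(((A:{a},B:{b}){s}:{e},C:{c}){s}:{f},D:{d});",       # caterpillar
]


class TestSubstitutionModel:
    @pytest.mark.parametrize("name", ["LG", "WAG", "JTT"])
    def test_shipped_matrices_normalised(self, name):
        m = cs.load_model(name)
        assert m.Q.shape == (20, 20)
        assert np.abs(m.Q.sum(axis=1)).max() < 1e-10
        assert -np.dot(m.pi, np.diag(m.Q)) == pytest.approx(1.0, abs=1e-10)
        assert abs(m.pi.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("t", [0.0, 0.01, 0.5, 3.0, 50.0])
    def test_transition_matrices_stochastic(self, lg, t):
        P = lg.transition_matrix(t)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0.0

    def test_plus_f_uniform_alignment(self, tmp_path):
        msa = cs.Msa([("a", cs.load_model("LG").alphabet),
                      ("b", cs.load_model("LG").alphabet)])
        freqs = empirical_frequencies(msa, pseudocount=0.0)
        assert np.allclose(freqs, 1 / 20)

    def test_two_state_toy_model_from_file(self, tmp_path, toy2):
        # alphabet switching: a custom 2-state model behaves like a CTMC
        P = toy2.transition_matrix(1e6)
        assert np.allclose(P, np.tile(toy2.pi, (2, 1)), atol=1e-8)

    def test_asymmetric_exchangeabilities_rejected(self):
        S = np.zeros((2, 2))
        S[0, 1] = 1.0
        with pytest.raises(cs.ValidationError):
            cs.SubstitutionModel(S, [0.5, 0.5], alphabet="AC")

    def test_non_simplex_frequencies_rejected(self):
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(cs.ValidationError):
            cs.SubstitutionModel(S, [0.5, 0.2], alphabet="AC")


class TestSiteLikelihood:
    def test_single_leaf_equals_prior(self, lg):
        t = cs.parse_newick("(A:0.3,B:0.1);")
        # both tips missing except A='A': likelihood = sum_j pi_j P_{jA}... so
        # instead use zero-length two-leaf identical tips for the closed form
        t0 = cs.parse_newick("(A:0.0,B:0.0);")
        iA = lg.alphabet.index("A")
        assert cs.site_likelihood(t0, {"A": "A", "B": "A"}, lg) == \
            pytest.approx(lg.pi[iA], abs=1e-12)
        assert cs.site_likelihood(t0, {"A": "A", "B": "C"}, lg) == \
            pytest.approx(0.0, abs=1e-12)

    def test_missing_data_marginalises_to_one(self, lg, quartet):
        pattern = {label: "-" for label in quartet.leaf_labels}
        assert cs.site_likelihood(quartet, pattern, lg) == \
            pytest.approx(1.0, abs=1e-10)

    def test_exhaustive_quartets_two_states(self, toy2):
        rng = np.random.default_rng(11)
        for shape in QUARTET_SHAPES:
            text = shape.format(a=rng.uniform(0.05, 0.5),
                                b=rng.uniform(0.05, 0.5),
                                c=rng.uniform(0.05, 0.5),
                                d=rng.uniform(0.05, 0.5),
                                e=rng.uniform(0.05, 0.5),
                                f=rng.uniform(0.05, 0.5), s=0.9)
            tree = cs.parse_newick(text)
            total = 0.0
            for pat in itertools.product(toy2.alphabet, repeat=4):
                col = dict(zip("ABCD", pat))
                got = cs.site_likelihood(tree, col, toy2)
                ref = enumerate_site_likelihood(tree, col, toy2)
                assert got == pytest.approx(ref, rel=1e-10)
                total += got
            assert total == pytest.approx(1.0, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_five_leaf_amino_acid_cases(self, lg, seed):
        rng = np.random.default_rng(seed)
        tree = cs.parse_newick(random_rooted_tree(list("ABCDE"), rng))
        for _ in range(5):
            col = {l: lg.alphabet[rng.integers(20)] for l in "ABCDE"}
            got = cs.site_likelihood(tree, col, lg)
            ref = enumerate_site_likelihood(tree, col, lg)
            assert got == pytest.approx(ref, rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_reroot_invariance_reversible_model(self, lg, seed):
        # total likelihood must not depend on root placement for reversible Q
        rng = np.random.default_rng(100 + seed)
        labels = list("ABCDE")
        tree = cs.parse_newick(random_rooted_tree(labels, rng))
        col = {l: lg.alphabet[rng.integers(20)] for l in labels}
        base = cs.site_likelihood(tree, col, lg)

        import dendropy
        dtree = dendropy.Tree.get(data=cs.write_newick(tree), schema="newick")
        edge = [e for e in dtree.preorder_edge_iter()
                if e.length and e.head_node.is_leaf()][0]
        dtree.reroot_at_edge(edge, length1=edge.length / 2,
                             length2=edge.length / 2)
        rerooted = cs.parse_newick(dtree.as_string(schema="newick")
                                   .replace("[&R] ", ""))
        assert cs.site_likelihood(rerooted, col, lg) == \
            pytest.approx(base, rel=1e-9)

    def test_gamma_rates_mean_of_categories(self, toy2, quartet):
        gamma = cs.SubstitutionModel(toy2.S, toy2.pi, alphabet="AC",
                                     gamma_shape=0.7, n_rate_categories=4)
        rates = gamma.rate_categories()
        assert rates.mean() == pytest.approx(1.0, rel=1e-9)
        col = {"A": "A", "B": "A", "C": "C", "D": "A"}
        per_cat = []
        for r in rates:
            scaled = cs.parse_newick(cs.write_newick(quartet))
            for node in scaled.nodes:
                node.length *= r
            per_cat.append(cs.site_likelihood(scaled, col, toy2))
        assert cs.site_likelihood(quartet, col, gamma) == \
            pytest.approx(np.mean(per_cat), rel=1e-9)

    def test_unknown_residue_rejected(self, lg, quartet):
        with pytest.raises(cs.ValidationError):
            cs.site_likelihood(quartet, {"A": "B", "B": "A", "C": "A", "D": "A"},
                               lg)


class TestMarginalAsr:
    def test_posteriors_sum_to_one(self, lg, quartet):
        msa = cs.Msa([("A", "KR"), ("B", "KG"), ("C", "K-"), ("D", "KR")])
        asr = cs.marginal_asr(quartet, msa, lg)
        for post in asr.posteriors.values():
            assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-8

    def test_conserved_site_reconstructed_confidently(self, lg):
        t = cs.parse_newick("((A:0.02,B:0.02)0.9:0.02,(C:0.02,D:0.02)0.9:0.02);")
        msa = cs.Msa([(x, "K") for x in "ABCD"])
        asr = cs.marginal_asr(t, msa, lg)
        for idx in asr.posteriors:
            assert asr.map_state[idx][0] == "K"
            assert asr.map_posterior[idx][0] > 0.99

    def test_long_branches_posterior_approaches_prior(self, lg):
        t = cs.parse_newick("((A:60,B:60)0.9:0.01,(C:60,D:60)0.9:0.01);")
        msa = cs.Msa([("A", "K"), ("B", "W"), ("C", "R"), ("D", "D")])
        asr = cs.marginal_asr(t, msa, lg)
        root_post = asr.posteriors[t.root.index][0]
        assert np.abs(root_post - lg.pi).max() < 1e-3

    def test_three_leaf_two_state_matches_bayes_rule(self, toy2):
        t = cs.parse_newick("(A:0.2,B:0.4,C:0.3);")
        col = {"A": "A", "B": "C", "C": "A"}
        asr = cs.marginal_asr(t, cs.Msa([(k, v) for k, v in col.items()]), toy2)
        # direct Bayes over the two root states
        num = []
        for i, _ in enumerate(toy2.alphabet):
            term = toy2.pi[i]
            for tip, length in (("A", 0.2), ("B", 0.4), ("C", 0.3)):
                P = toy2.transition_matrix(length)
                term *= P[i, toy2.alphabet.index(col[tip])]
            num.append(term)
        expected = np.array(num) / sum(num)
        assert np.allclose(asr.posteriors[t.root.index][0], expected,
                           atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_quartets(self, lg, seed):
        rng = np.random.default_rng(300 + seed)
        tree = cs.parse_newick(random_rooted_tree(list("ABCD"), rng))
        col = {l: lg.alphabet[rng.integers(20)] for l in "ABCD"}
        msa = cs.Msa([(l, col[l]) for l in tree.leaf_labels])
        asr = cs.marginal_asr(tree, msa, lg)
        ref = enumerate_posteriors(tree, col, lg)
        for idx, expected in ref.items():
            assert np.abs(asr.posteriors[idx][0] - expected).max() < 1e-8

    def test_tie_flag_on_symmetric_pattern(self):
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        sym = cs.SubstitutionModel(S, [0.5, 0.5], alphabet="AC")
        t = cs.parse_newick("((A:0.2,B:0.2)0.9:0.1,(C:0.2,D:0.2)0.9:0.1);")
        msa = cs.Msa([("A", "A"), ("B", "C"), ("C", "A"), ("D", "C")])
        asr = cs.marginal_asr(t, msa, sym)
        assert bool(asr.tied[t.root.index][0])
        assert asr.map_state[t.root.index][0] == "A"  # lexicographic break

    def test_map_accuracy_improves_with_shorter_branches(self, lg):
        accuracies = []
        for scale in (1.6, 0.4, 0.1):
            cfg = default_config(seed=42, n_sites=300)
            for node in cfg.tree.nodes:
                node.length *= scale
            msa, truth = simulate_alignment(cfg)
            asr = cs.marginal_asr(cfg.tree, msa, cfg.model)
            root = cfg.tree.root.index
            acc = np.mean([a == b for a, b in
                           zip(asr.map_sequence(root), truth[root])])
            accuracies.append(acc)
        assert accuracies[0] < accuracies[-1]
        assert accuracies == sorted(accuracies)


class TestFitBranchScale:
    def test_recovers_unit_scale_from_simulation(self):
        cfg = default_config(seed=5, n_sites=1000)
        msa, _ = simulate_alignment(cfg)
        c = cs.fit_branch_scale(cfg.tree, msa, cfg.model)
        assert 0.5 <= c <= 2.0

    def test_identical_sequences_return_one_with_warning(self, lg, quartet):
        msa = cs.Msa([(x, "KKKK") for x in "ABCD"])
        with pytest.warns(UserWarning):
            assert cs.fit_branch_scale(quartet, msa, lg) == 1.0

    def test_equivariance_under_branch_doubling(self):
        cfg = default_config(seed=6, n_sites=1000)
        msa, _ = simulate_alignment(cfg)
        c1 = cs.fit_branch_scale(cfg.tree, msa, cfg.model)
        halved = cs.parse_newick(cs.write_newick(cfg.tree))
        for node in halved.nodes:
            node.length *= 0.5
        c2 = cs.fit_branch_scale(halved, msa, cfg.model)
        assert c2 == pytest.approx(2 * c1, rel=0.05)

    def test_fitted_likelihood_not_below_baseline(self):
        cfg = default_config(seed=7, n_sites=200)
        msa, _ = simulate_alignment(cfg)
        stretched = cs.parse_newick(cs.write_newick(cfg.tree))
        for node in stretched.nodes:
            node.length *= 3.0
        c = cs.fit_branch_scale(stretched, msa, cfg.model)
        assert log_likelihood(stretched, msa, cfg.model, branch_scale=c) >= \
            log_likelihood(stretched, msa, cfg.model, branch_scale=1.0)
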