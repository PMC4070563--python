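"""Kraskov MI estimation and the ARACNE / CLR / MRNET / threshold chain."""

import numpy as np
import pytest

from coexcis import (
    MiConfig,
    MutualInfoNetwork,
    SimilarityMatrix,
    aracne_prune,
    clr_transform,
    fraction_threshold_network,
    kraskov_mi,
    kraskov_mi_all,
    mrnet_build,
    planted_block_truth,
    synth_expression,
)
from conftest import random_ternary
from oracles import bf_aracne, bf_clr, bf_mrnet


def _mi_sim(ids, entries):
    n = len(ids)
    w = np.zeros((n, n))
    idx = {g: i for i, g in enumerate(ids)}
    for (a, b), v in entries.items():
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = v
    return SimilarityMatrix(ids, w, "mi")


class TestKraskovMi:
    def test_independent_uniform_near_zero(self, rng):
        x, y = rng.random(1000), rng.random(1000)
        assert abs(kraskov_mi(x, y, k=3)) < 0.05

    def test_bivariate_gaussian_closed_form(self, rng):
        rho = 0.9
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=2000)
        truth = -0.5 * np.log(1 - rho**2)  # 0.8304 nats
        assert kraskov_mi(xy[:, 0], xy[:, 1], k=3) == pytest.approx(truth, abs=0.1)

    def test_agrees_with_sklearn_estimator(self, rng):
        """Independent cross-check against sklearn's Kraskov-based estimator."""
        from sklearn.feature_selection import mutual_info_regression

        rho = 0.7
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=1500)
        ours = kraskov_mi(xy[:, 0], xy[:, 1], k=3)
        theirs = mutual_info_regression(
            xy[:, :1], xy[:, 1], n_neighbors=3, random_state=0
        )[0]
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_identical_profiles_dominate(self, rng):
        x = rng.random(300)
        y = x + rng.normal(0, 1e-12, size=300)
        z = rng.random(300)
        assert kraskov_mi(x, y, k=3) > kraskov_mi(x, z, k=3)

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            kraskov_mi(np.arange(5.0), np.arange(5.0), k=5)

    def test_all_pairs_symmetric(self):
        m = random_ternary(6, 40, seed=31)
        s = kraskov_mi_all(m, MiConfig(seed=1))
        assert np.allclose(s.weights, s.weights.T)
        assert s.kind == "mi"

    def test_jitter_seed_stability(self):
        """Estimates for a co-expressed pair vary < 10% (CV) across jitter seeds.

        The CV is a relative measure, so it is only meaningful for a pair
        whose MI is well away from zero; independent pairs have estimates
        fluctuating around 0 and an unbounded CV by construction.
        """
        truth = planted_block_truth(1, 2, 271, 0.05, seed=32)
        m = synth_expression(2, 271, truth, seed=33)
        estimates = [
            kraskov_mi_all(m, MiConfig(seed=s)).weights[0, 1] for s in range(10)
        ]
        cv = np.std(estimates) / abs(np.mean(estimates))
        assert cv < 0.10

    def test_recovers_planted_structure(self):
        truth = planted_block_truth(2, 5, 80, 0.1, seed=34)
        m = synth_expression(10, 80, truth, seed=35)
        s = kraskov_mi_all(m, MiConfig(seed=36))
        labels = [truth.module_assignments[g] for g in m.gene_ids]
        within, between = [], []
        for i in range(10):
            for j in range(i + 1, 10):
                (within if labels[i] == labels[j] else between).append(s.weights[i, j])
        assert np.mean(within) > np.mean(between)


class TestAracne:
    def test_additive_triple_by_hand(self):
        s = _mi_sim(list("abc"), {("a", "b"): 3, ("b", "c"): 2, ("a", "c"): 1})
        out = aracne_prune(s, "additive", 0.0)
        w = out.weights
        assert w[0, 2] == 0  # ac removed: 1 < min(3, 2)
        assert w[0, 1] == 3 and w[1, 2] == 2

    def test_multiplicative_tolerance_keeps_weak_edge(self):
        s = _mi_sim(list("abc"), {("a", "b"): 3, ("b", "c"): 2, ("a", "c"): 1})
        out = aracne_prune(s, "multiplicative", 0.3)
        assert out.weights[0, 2] == 1  # 1 >= 0.3 * min(3, 2)

    def test_two_genes_unchanged(self):
        s = _mi_sim(list("ab"), {("a", "b"): 1.5})
        assert np.array_equal(aracne_prune(s, "additive", 0.0).weights, s.weights)

    def test_matches_triple_scan_oracle(self):
        g = np.random.default_rng(37)
        for mode, tol in (("additive", 0.0), ("additive", 0.1),
                          ("multiplicative", 1.0), ("multiplicative", 0.5)):
            w = g.random((8, 8))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            s = SimilarityMatrix([f"g{i}" for i in range(8)], w, "mi")
            np.testing.assert_allclose(
                aracne_prune(s, mode, tol).weights, bf_aracne(w, mode, tol)
            )

    def test_output_edges_subset_of_input(self):
        g = np.random.default_rng(38)
        w = g.random((10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        s = SimilarityMatrix([f"g{i}" for i in range(10)], w, "mi")
        out = aracne_prune(s, "multiplicative", 1.0)
        assert ((out.weights != 0) <= (s.weights != 0)).all()

    def test_strict_variants_coincide_without_ties(self):
        g = np.random.default_rng(39)
        w = g.random((9, 9)) + 0.01
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        s = SimilarityMatrix([f"g{i}" for i in range(9)], w, "mi")
        np.testing.assert_allclose(
            aracne_prune(s, "additive", 0.0).weights,
            aracne_prune(s, "multiplicative", 1.0).weights,
        )


class TestClr:
    def test_all_equal_mi_gives_zero_scores(self):
        s = _mi_sim(list("abcd"), {(a, b): 1.0 for a in "abcd" for b in "abcd" if a < b})
        assert (clr_transform(s).weights == 0).all()

    def test_three_gene_hand_oracle(self):
        # rows: a -> [2,1] mu 1.5 sd .5; z_a(b)=1, z_b(a)=1; c's row sd=0
        s = _mi_sim(list("abc"), {("a", "b"): 2, ("a", "c"): 1, ("b", "c"): 1})
        out = clr_transform(s).weights
        assert out[0, 1] == pytest.approx(np.sqrt(2))
        assert out[0, 2] == pytest.approx(0.0)
        assert out[1, 2] == pytest.approx(0.0)

    def test_matches_brute_force(self):
        g = np.random.default_rng(40)
        w = g.random((7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        s = SimilarityMatrix([f"g{i}" for i in range(7)], w, "mi")
        np.testing.assert_allclose(clr_transform(s).weights, bf_clr(w), atol=1e-12)

    def test_symmetric_output(self):
        g = np.random.default_rng(41)
        w = g.random((6, 6))
        w = (w + w.T) / 2
        s = SimilarityMatrix([f"g{i}" for i in range(6)], w, "mi")
        out = clr_transform(s).weights
        assert np.allclose(out, out.T)
        assert clr_transform(s).kind == "clr_score"


class TestMrnet:
    def test_two_genes_weight_equals_mi(self):
        s = _mi_sim(list("ab"), {("a", "b"): 0.7})
        assert mrnet_build(s).weights[0, 1] == pytest.approx(0.7)

    def test_chain_indirect_edge_weaker(self):
        s = _mi_sim(
            list("xzy"), {("x", "z"): 0.8, ("z", "y"): 0.7, ("x", "y"): 0.2}
        )
        out = mrnet_build(s).weights
        idx = {g: i for i, g in enumerate(s.gene_ids)}
        xy = out[idx["x"], idx["y"]]
        assert xy < out[idx["x"], idx["z"]]
        assert xy < out[idx["z"], idx["y"]]

    def test_nonnegative_and_matches_oracle(self):
        g = np.random.default_rng(42)
        w = g.random((8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        s = SimilarityMatrix([f"g{i}" for i in range(8)], w, "mi")
        out = mrnet_build(s).weights
        assert (out >= 0).all()
        np.testing.assert_allclose(out, bf_mrnet(w), atol=1e-12)


class TestFractionThreshold:
    def test_example_edges(self):
        s = _mi_sim(list("abc"), {("a", "b"): 1.0, ("a", "c"): 0.85, ("b", "c"): 0.5})
        net = fraction_threshold_network(s, 0.8)
        assert {tuple(sorted(e)) for e in net.edges} == {("a", "b"), ("a", "c")}
        assert set(net.nodes) == {"a", "b", "c"}

    def test_fraction_one_keeps_only_maxima(self):
        s = _mi_sim(list("abc"), {("a", "b"): 1.0, ("a", "c"): 0.85, ("b", "c"): 0.5})
        net = fraction_threshold_network(s, 1.0)
        assert {tuple(sorted(e)) for e in net.edges} == {("a", "b")}

    def test_isolated_genes_dropped(self):
        s = _mi_sim(list("abcd"), {("a", "b"): 1.0})
        net = fraction_threshold_network(s, 0.9)
        assert set(net.nodes) == {"a", "b"}

    def test_matches_brute_force_filter(self):
        g = np.random.default_rng(43)
        w = g.random((10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        s = SimilarityMatrix([f"g{i}" for i in range(10)], w, "mi")
        for frac in (0.8, 0.9):
            thr = frac * w[~np.eye(10, dtype=bool)].max()
            expected = {
                (f"g{i}", f"g{j}")
                for i in range(10)
                for j in range(i + 1, 10)
                if w[i, j] >= thr
            }
            net = fraction_threshold_network(s, frac)
            assert {tuple(sorted(e)) for e in net.edges} == expected

    def test_all_zero_matrix_errors(self):
        s = SimilarityMatrix(["a", "b"], np.zeros((2, 2)), "mi")
        with pytest.raises(ValueError, match="no edges"):
            fraction_threshold_network(s, 0.8)


class TestMutualInfoNetworkEstimator:
    def test_fit_builds_graph(self):
        truth = planted_block_truth(2, 6, 60, 0.05, seed=44)
        m = synth_expression(16, 60, truth, seed=45)
        est = MutualInfoNetwork(
            algorithm="aracne_multiplicative", fraction=0.8, random_state=46
        ).fit(m)
        assert est.mi_.kind == "mi"
        assert est.graph_.number_of_edges() > 0
        # thresholding drops isolated genes: never more nodes than genes
        assert est.graph_.number_of_nodes() <= m.n_genes

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError, match="algorithm"):
            MutualInfoNetwork(algorithm="nope").fit(np.zeros((3, 4)))
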