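"""Evaluation metrics against brute-force oracles."""

import numpy as np
import pytest

import multiomesim.metrics as mt


class TestRSquared:
    def test_perfect_and_affine(self, rng):
        t = rng.uniform(size=30)
        assert mt.r_squared(t, t) == pytest.approx(1.0)
        assert mt.r_squared(t, 3 * t - 2) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        r = np.random.default_rng(0)
        assert mt.r_squared(r.uniform(size=10_000),
                            r.uniform(size=10_000)) < 0.01

    def test_constant_input_undefined(self):
        with pytest.raises(mt.UndefinedMetric):
            mt.r_squared(np.ones(5), np.arange(5.0))


class TestKnnPurity:
    def test_identical_orderings_score_one(self):
        t = np.arange(20.0)
        np.testing.assert_allclose(mt.knn_purity(t, t, k=5), 1.0)

    def test_reversed_line_endpoints_score_one(self):
        t = np.arange(10.0)
        out = mt.knn_purity(t, t[::-1] * -1 + 100, k=3)
        # reversing pseudotime preserves neighbourhood structure on a line
        assert out[0] == pytest.approx(1.0) and out[-1] == pytest.approx(1.0)
        assert np.all(out > 0)

    def test_random_ordering_mean_near_k_over_n(self):
        r = np.random.default_rng(1)
        n, k = 600, 30
        out = mt.knn_purity(np.arange(float(n)), r.uniform(size=n), k=k)
        # Jaccard of two ~independent k-subsets concentrates near
        # (k/(2n-k)) ~ k/2n for k << n; allow a loose band
        assert out.mean() < 2.5 * k / n


class TestGraphConnectivity:
    def test_fully_connected_graph_scores_one(self):
        adj = np.ones((6, 6)) - np.eye(6)
        assert mt.graph_connectivity(adj, ["a"] * 3 + ["b"] * 3) == 1.0

    def test_split_type_contributes_half(self):
        adj = np.zeros((4, 4))
        adj[2, 3] = adj[3, 2] = 1  # type b connected, type a split in two
        out = mt.graph_connectivity(adj, ["a", "a", "b", "b"])
        assert out == pytest.approx((0.5 + 1.0) / 2)

    def test_matches_bruteforce_component_search(self, rng):
        import networkx as nx

        n = 15
        adj = (rng.uniform(size=(n, n)) < 0.15).astype(int)
        adj = ((adj + adj.T) > 0).astype(int)
        np.fill_diagonal(adj, 0)
        types = rng.choice(["a", "b", "c"], size=n)
        expected = []
        for t in ["a", "b", "c"]:
            idx = [i for i in range(n) if types[i] == t]
            sub = nx.from_numpy_array(adj[np.ix_(idx, idx)])
            expected.append(max(len(c) for c in nx.connected_components(sub))
                            / len(idx))
        assert mt.graph_connectivity(adj, types) == pytest.approx(
            np.mean(expected))


class TestBatchAsw:
    def test_mixed_batches_score_near_one(self):
        r = np.random.default_rng(2)
        emb = r.normal(size=(200, 3))
        batches = np.arange(200) % 2
        out = mt.batch_asw(emb, batches, ["t"] * 200)
        assert out > 0.85

    def test_separated_batches_score_near_zero(self):
        r = np.random.default_rng(3)
        emb = r.normal(size=(100, 2)) + np.where(
            (np.arange(100) % 2 == 0)[:, None], 50.0, 0.0)
        out = mt.batch_asw(emb, np.arange(100) % 2, ["t"] * 100)
        assert out < 0.1

    def test_single_batch_undefined(self):
        with pytest.raises(mt.UndefinedMetric):
            mt.batch_asw(np.zeros((4, 2)), [0, 0, 0, 0], ["t"] * 4)


class TestVelocityCosine:
    def test_limits(self, rng):
        v = rng.normal(size=(10, 4))
        assert mt.velocity_cosine(v, v) == pytest.approx(1.0)
        assert mt.velocity_cosine(v, -v) == pytest.approx(-1.0)
        assert mt.velocity_cosine(v, 2 * v) == pytest.approx(1.0)

    def test_zero_rows_skipped_with_warning(self, rng):
        v = rng.normal(size=(5, 3))
        u = v.copy()
        u[0] = 0.0
        with pytest.warns(UserWarning, match="skipped"):
            out = mt.velocity_cosine(v, u)
        assert out == pytest.approx(1.0)

    def test_smoothing_improves_cosine_as_a_trend(self, rng):
        # noisy copies of a smooth velocity field over >= 20 replicates
        import multiomesim as m

        wins = 0
        reps = 20
        for rep in range(reps):
            r = np.random.default_rng(rep)
            emb = r.uniform(size=(150, 2))
            true_v = np.column_stack([np.sin(3 * emb[:, 0]),
                                      np.cos(3 * emb[:, 1])])
            noisy = true_v + r.normal(0, 1.0, size=true_v.shape)
            before = mt.velocity_cosine(true_v, noisy)
            after = mt.velocity_cosine(true_v,
                                       m.knn_smooth_velocity(noisy, emb, k=10))
            wins += after >= before
        assert wins / reps > 0.7


class TestAuprcAuroc:
    def test_perfect_ranking(self):
        auprc, auroc, ratio = mt.auprc_auroc([0, 0, 1, 1],
                                             [0.1, 0.2, 0.8, 0.9])
        assert auroc == 1.0 and auprc == 1.0
        assert ratio == pytest.approx(1.0 / 0.5)

    def test_random_scores_give_ratio_one(self):
        r = np.random.default_rng(4)
        y = r.uniform(size=20_000) < 0.1
        _, _, ratio = mt.auprc_auroc(y, r.uniform(size=20_000))
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_tiny_instance_matches_threshold_sweep(self):
        y = np.array([1, 0, 1, 0])
        s = np.array([0.9, 0.8, 0.4, 0.1])
        auprc, auroc, _ = mt.auprc_auroc(y, s)
        # brute force: AP = sum over positives of precision at their rank
        # ranks (desc): 0.9 (P), 0.8 (N), 0.4 (P), 0.1 (N)
        ap = 0.5 * (1 / 1 + 2 / 3)
        # AUROC = P(score_pos > score_neg) over the 4 pos/neg pairs
        pairs = [(0.9, 0.8), (0.9, 0.1), (0.4, 0.8), (0.4, 0.1)]
        auc = np.mean([p > n for p, n in pairs])
        assert auprc == pytest.approx(ap)
        assert auroc == pytest.approx(auc)

    def test_single_class_undefined(self):
        with pytest.raises(mt.UndefinedMetric):
            mt.auprc_auroc([1, 1, 1], [0.1, 0.2, 0.3])


class TestBonferroni:
    def test_definition(self):
        np.testing.assert_allclose(mt.bonferroni([0.01, 0.5]), [0.02, 1.0])

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(mt.bonferroni([0.03]), [0.03])

    def test_saturates_at_one(self):
        np.testing.assert_allclose(mt.bonferroni([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mt.bonferroni([1.2])


class TestSummaryStats:
    def test_all_zero_matrix(self):
        out = mt.summary_stats(np.zeros((3, 4)))
        np.testing.assert_array_equal(out["zero_prop_per_gene"], 1.0)
        np.testing.assert_array_equal(out["mean_per_gene"], 0.0)

    def test_identity_like_matrix(self):
        out = mt.summary_stats(np.eye(2))
        np.testing.assert_array_equal(out["lib_size_per_cell"], [1, 1])
        np.testing.assert_array_equal(out["zero_prop_per_gene"], [0.5, 0.5])

    def test_matches_bruteforce(self, rng):
        x = rng.poisson(2.0, size=(8, 5)).astype(float)
        out = mt.summary_stats(x)
        np.testing.assert_allclose(out["lib_size_per_cell"],
                                   [sum(x[i]) for i in range(8)])
        np.testing.assert_allclose(out["var_per_gene"],
                                   [np.var(x[:, j]) for j in range(5)])

    def test_atac_variant(self, rng):
        x = rng.exponential(size=(6, 7))
        out = mt.summary_stats(x, modality="atac")
        assert set(out) == {"lib_size_per_cell", "cell_sparsity", "peak_mean"}
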