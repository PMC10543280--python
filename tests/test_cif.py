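"""Cell identity factors, gene identity vectors and the tree random walk."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import multiomesim as m
from multiomesim import cif


class TestNondiffCif:
    def test_zero_sigma_gives_exact_ones(self, rng):
        mat = cif.sample_nondiff_cif(10, 4, 0.0, rng)
        np.testing.assert_array_equal(mat, np.ones((10, 4)))

    def test_sample_sd_matches_sigma(self, rng):
        mat = cif.sample_nondiff_cif(1000, 100, 0.5, rng)
        assert mat.std() == pytest.approx(0.5, rel=0.01)
        assert mat.mean() == pytest.approx(1.0, abs=0.01)

    def test_zero_width_segment_allowed(self, rng):
        assert cif.sample_nondiff_cif(10, 0, 0.1, rng).shape == (10, 0)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            cif.sample_nondiff_cif(10, 4, -0.1, rng)


class TestDiffCif:
    def test_walk_variance_matches_branch_distance(self):
        # Brownian-walk oracle: Var at depth D equals D (averaged over
        # independent field realisations)
        tree = m.builtin_tree("Phyla1")  # depth 2 path
        vals = []
        for seed in range(3000):
            f = cif.BrownianTreeField(tree, 1, np.random.default_rng(seed))
            vals.append(f.at(0, 2.0)[0])
        assert np.var(vals) == pytest.approx(2.0, rel=0.1)
        vals1 = [cif.BrownianTreeField(tree, 1, np.random.default_rng(s)).at(0, 1.0)[0]
                 for s in range(3000)]
        assert np.var(vals1) == pytest.approx(1.0, rel=0.1)

    def test_same_position_same_value(self, rng):
        tree = m.builtin_tree("Phyla3")
        f = cif.BrownianTreeField(tree, 5, rng)
        np.testing.assert_array_equal(f.at(0, 1.3), f.at(0, 1.3))

    def test_zero_sigma_cells_at_same_position_identical(self):
        tree = m.builtin_tree("Phyla1")
        rng = np.random.default_rng(0)
        meta = cif.CellMeta(np.array(["A", "A"], dtype=object),
                            np.array([1.0, 1.0]), np.array([0, 0]))
        mat, _ = cif.sample_diff_cif(tree, 2, 4, 0.0, "continuous", rng,
                                     meta_pos=(meta, np.array([1.0, 1.0])))
        np.testing.assert_array_equal(mat[0], mat[1])

    def test_discrete_balanced_assignment(self, rng):
        tree = m.builtin_tree("Phyla5")
        meta, _ = cif.assign_cells(tree, 500, "discrete", rng)
        _, counts = np.unique(list(meta.cell_type), return_counts=True)
        assert list(counts) == [100] * 5

    def test_continuous_zero_width_warns(self, rng):
        tree = m.builtin_tree("Phyla1")
        with pytest.warns(UserWarning, match="trajectory"):
            cif.sample_diff_cif(tree, 5, 0, 0.1, "continuous", rng)

    def test_larger_rd_increases_tree_position_variance_share(self):
        # fraction of total CIF variance explained by the cell's leaf type
        # strictly grows with the diff-to-nondiff ratio, sigma_cif matched
        tree = m.builtin_tree("Phyla5")

        def share(rd, seed):
            ncif = 20
            n_diff = round(rd * ncif)
            r = np.random.default_rng(seed)
            meta, pos = cif.assign_cells(tree, 200, "discrete", r)
            nd = cif.sample_nondiff_cif(200, ncif - n_diff, 0.3, r)
            diff, _ = cif.sample_diff_cif(tree, 200, n_diff, 0.3, "discrete",
                                          r, meta_pos=(meta, pos))
            full = np.hstack([nd, diff])
            types = np.asarray(list(meta.cell_type))
            within = np.mean([full[types == t].var(axis=0).mean()
                              for t in np.unique(types)])
            return 1.0 - within / full.var(axis=0).mean()

        low = np.mean([share(0.2, s) for s in range(5)])
        high = np.mean([share(0.8, s) for s in range(5)])
        assert high > low


class TestTfCif:
    def test_equal_tf_expression_gives_half(self):
        x = np.zeros(10)
        x[[0, 2, 4]] = 3.0
        out = cif.update_tf_cif(x, [1, 3, 5])
        np.testing.assert_allclose(out, 0.5)

    def test_single_nonzero_tf(self):
        n = 4
        x = np.zeros(10)
        x[0] = 2.0
        out = cif.update_tf_cif(x, [1, 2, 3, 4])
        assert out[0] == pytest.approx(n / (n + 1))
        np.testing.assert_array_equal(out[1:], 0.0)

    def test_all_zero_expression_gives_zeros(self):
        out = cif.update_tf_cif(np.zeros(5), [1, 2])
        np.testing.assert_array_equal(out, 0.0)

    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2,
                    max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_output_always_in_unit_interval(self, xs):
        out = cif.update_tf_cif(np.array(xs), list(range(1, len(xs) + 1)))
        assert np.all(out >= 0) and np.all(out < 1)


class TestGiv:
    def test_p0_one_gives_all_zeros(self, rng):
        assert cif.sample_giv(20, 20, 1.0, 0, 1, rng).sum() == 0

    def test_nonzero_fraction_matches_p0(self, rng):
        mat = cif.sample_giv(500, 200, 0.7, 0, 1, rng)
        assert (mat != 0).mean() == pytest.approx(0.3, abs=0.01)

    def test_p0_zero_gives_no_zeros(self, rng):
        assert np.all(cif.sample_giv(50, 50, 0.0, 5, 1, rng) != 0)

    def test_invalid_p0_rejected(self, rng):
        with pytest.raises(ValueError):
            cif.sample_giv(5, 5, 1.5, 0, 1, rng)


class TestDiffGiv:
    def test_unit_effect_target_copies_tf_column(self, rng):
        grn = m.load_grn([(1, 2, 1.0)], 2)
        out = cif.build_diff_giv(grn, 6, rng)
        np.testing.assert_allclose(out[:, 1], out[:, 0])

    def test_two_regulators_sum(self, rng):
        grn = m.load_grn([(1, 3, 1.0), (2, 3, 1.0)], 3)
        out = cif.build_diff_giv(grn, 8, rng)
        np.testing.assert_allclose(out[:, 2], out[:, 0] + out[:, 1])

    def test_every_tf_column_has_exactly_two_entries(self, rng, small_grn):
        out = cif.build_diff_giv(small_grn, 10, rng)
        # gene 1 is a pure TF; gene 2 is TF and target (blended column)
        assert (out[:, 0] != 0).sum() == 2
        assert set(np.unique(out[:, 0])) == {0.0, 0.2}

    def test_narrow_diff_segment_rejected(self, rng, small_grn):
        with pytest.raises(ValueError):
            cif.build_diff_giv(small_grn, 1, rng)


class TestEvolveGrn:
    def test_zero_rate_keeps_grn_identical(self, rng, small_grn):
        series = cif.evolve_grn(small_grn, 5, 0.0, rng)
        assert len(series) == 5
        for g in series:
            np.testing.assert_array_equal(g.mtg, small_grn.mtg)

    def test_deletion_only_shrinks_monotonically(self, rng, small_grn):
        series = cif.evolve_grn(small_grn, 6, 1.0, rng, allow_add=False)
        sizes = [len(g.edges) for g in series]
        assert sizes[0] == 5 and sizes[1] == 0  # rate 1 deletes everything

    def test_partial_deletion_markov_oracle(self):
        # expected surviving edges after k steps of independent deletion at
        # rate p is n0 * (1-p)^k
        p, n0, k, reps = 0.3, 5, 4, 400
        grn = m.load_grn([(1, g, 1.0) for g in range(2, 2 + n0)], 10)
        sizes = []
        for seed in range(reps):
            series = cif.evolve_grn(grn, k + 1, p,
                                    np.random.default_rng(seed),
                                    allow_add=False)
            sizes.append(len(series[-1].edges))
        assert np.mean(sizes) == pytest.approx(n0 * (1 - p) ** k, rel=0.1)


class TestAssembly:
    def test_widths_add_up(self, rng):
        out = cif.assemble_cif(np.ones((3, 2)), np.ones((3, 2)),
                               np.zeros((3, 0)), np.zeros((3, 0)))
        assert out.shape == (3, 4)

    def test_mismatched_cells_rejected(self):
        with pytest.raises(ValueError):
            cif.assemble_cif(np.ones((3, 2)), np.ones((4, 2)),
                             np.zeros((3, 0)), np.zeros((3, 0)))

    def test_product_matches_bruteforce_multiply(self, rng):
        a = rng.normal(size=(3, 4))
        b = rng.normal(size=(4, 2))
        c1 = cif.assemble_cif(a[:, :2], a[:, 2:], np.zeros((3, 0)),
                              np.zeros((3, 0)))
        g1 = cif.assemble_giv(b[:2], b[2:], np.zeros((0, 2)),
                              np.zeros((0, 2)))
        expected = np.array([[sum(a[i, k] * b[k, j] for k in range(4))
                              for j in range(2)] for i in range(3)])
        np.testing.assert_allclose(c1 @ g1, expected)


class TestCellSpecificGrnPipeline:
    def test_evolving_grn_run_exports_per_cell_truth(self):
        grn = m.load_grn([(1, 3, 2.0), (1, 4, 3.0), (2, 5, 1.5),
                          (2, 6, 4.0)], 10)
        cfg = m.SimConfig(ncell=40, ngene=10, ncif=10, grn=grn,
                          grn_change_rate=0.05, seed=2)
        res = m.simulate(cfg)
        assert res.grn_series is not None and len(res.grn_series) == 40
        assert all(g.tf_ids == grn.tf_ids for g in res.grn_series)
        assert np.all(res.counts >= 0)
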