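"""Grid placement, layouts, CCI truth sampling and the stepwise simulation."""

import numpy as np
import pytest

import multiomesim as m
from multiomesim import fixtures, spatial


def _truth_for(types, rows_by_pair):
    return spatial.CciTruth({tuple(sorted(k)): tuple(v)
                             for k, v in rows_by_pair.items()})


class TestGrid:
    @pytest.mark.parametrize("ncell,k", [(1000, 50), (1, 2), (100, 16)])
    def test_capacity_rule(self, ncell, k):
        assert spatial.init_grid(ncell).k == k

    def test_capacity_below_100_rejected(self):
        with pytest.raises(ValueError):
            spatial.init_grid(10, capacity_pct=50)

    def test_occupancy_injective(self, rng):
        state = spatial.init_grid(30)
        types = {}
        for i in range(30):
            spatial.place_cell(state, i, "t", types, 0.5, rng)
            types[i] = "t"
        assert len(set(state.positions.values())) == 30

    def test_full_grid_rejected(self, rng):
        state = spatial.SpatialState(k=1)
        state.place(0, (0, 0))
        with pytest.raises(ValueError, match="full"):
            spatial.place_cell(state, 1, "t", {0: "t"}, 0.5, rng)


class TestPlacement:
    def test_pn_one_forces_adjacency_when_possible(self, rng):
        for _ in range(20):
            state = spatial.init_grid(9)
            state.place(0, (2, 2))
            pos = spatial.place_cell(state, 1, "t", {0: "t"}, 1.0, rng)
            assert abs(pos[0] - 2) + abs(pos[1] - 2) == 1

    def test_empty_grid_places_uniformly(self, rng):
        state = spatial.init_grid(5)
        pos = spatial.place_cell(state, 0, "t", {}, 1.0, rng)
        assert pos in state.occupancy

    def test_affinity_orders_same_type_adjacency(self):
        # pn=1 runs cluster same-type cells more than pn=0.8 runs
        def same_type_fraction(pn, seed):
            rng = np.random.default_rng(seed)
            state = spatial.init_grid(300)
            types = {}
            labels = [f"t{i % 3}" for i in range(300)]
            for i in range(300):
                spatial.place_cell(state, i, labels[i], types, pn, rng)
                types[i] = labels[i]
            same = total = 0
            for i in range(300):
                for j in spatial.neighbors(state, i):
                    total += 1
                    same += labels[i] == labels[j]
            return same / total

        f1 = np.mean([same_type_fraction(1.0, s) for s in range(5)])
        f08 = np.mean([same_type_fraction(0.8, s) for s in range(5)])
        assert f1 > f08


class TestNeighbors:
    def test_isolated_cell_has_no_neighbors(self):
        state = spatial.init_grid(20)
        state.place(0, (5, 5))
        assert spatial.neighbors(state, 0) == []

    def test_fully_surrounded_cell_has_four(self):
        state = spatial.init_grid(20)
        state.place(0, (5, 5))
        for i, (dr, dc) in enumerate([(-1, 0), (1, 0), (0, -1), (0, 1)], 1):
            state.place(i, (5 + dr, 5 + dc))
        assert len(spatial.neighbors(state, 0)) == 4

    def test_diagonal_cell_excluded_at_radius_one(self):
        state = spatial.init_grid(20)
        state.place(0, (5, 5))
        state.place(1, (6, 6))
        assert spatial.neighbors(state, 0) == []

    def test_symmetry(self, rng):
        state = spatial.init_grid(40)
        types = {}
        for i in range(40):
            spatial.place_cell(state, i, "t", types, 0.7, rng)
            types[i] = "t"
        for i in range(40):
            for j in spatial.neighbors(state, i):
                assert i in spatial.neighbors(state, j)


class TestPrelayout:
    def test_islands_form_one_connected_component(self, rng):
        types = ["A"] * 40 + ["B"] * 60
        state = spatial.init_grid(100)
        spatial.prelayout("islands", types, state, rng, island_types=["A"],
                          randomize_frac=0.0)
        apos = {state.positions[i] for i in range(40)}
        # flood fill over 4-adjacency
        seen = {next(iter(apos))}
        frontier = list(seen)
        while frontier:
            r, c = frontier.pop()
            for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                p = (r + dr, c + dc)
                if p in apos and p not in seen:
                    seen.add(p)
                    frontier.append(p)
        assert seen == apos

    def test_layers_keep_types_contiguous(self, rng):
        types = ["A"] * 30 + ["B"] * 30 + ["C"] * 30
        state = spatial.init_grid(90)
        spatial.prelayout("layers", types, state, rng, randomize_frac=0.0)
        assert len(state.positions) == 90

    def test_zero_randomization_is_deterministic(self):
        types = ["A"] * 20 + ["B"] * 20
        p1, p2 = [], []
        for out in (p1, p2):
            state = spatial.init_grid(40)
            spatial.prelayout("layers", types, state,
                              np.random.default_rng(9), randomize_frac=0.0)
            out.append(dict(state.positions))
        assert p1 == p2

    def test_unknown_layout_rejected(self, rng):
        with pytest.raises(ValueError):
            spatial.prelayout("spiral", ["A"], spatial.init_grid(1), rng)


class TestCciTruth:
    def test_full_range_uses_all_rows(self, rng, small_lr):
        truth = spatial.sample_cci_truth(small_lr, ["a", "b"], rng,
                                         pairs_range=(2, 2))
        assert truth.rows_for_types("a", "b") == (0, 1)

    def test_five_types_give_ten_pairs(self, rng):
        db = m.load_lr_database([(i, i + 10, 1.0) for i in range(1, 7)])
        truth = spatial.sample_cci_truth(db, [f"t{i}" for i in range(5)], rng)
        assert len(truth.type_level) == 10

    def test_mean_rows_per_pair_matches_uniform_expectation(self, rng):
        db = m.load_lr_database([(i, i + 50, 1.0) for i in range(1, 7)])
        types = [f"t{i}" for i in range(46)]  # 1035 pairs
        truth = spatial.sample_cci_truth(db, types, rng, pairs_range=(3, 6))
        sizes = [len(v) for v in truth.type_level.values()]
        assert np.mean(sizes) == pytest.approx(4.5, rel=0.02)

    def test_range_exceeding_database_rejected(self, rng, small_lr):
        with pytest.raises(ValueError):
            spatial.sample_cci_truth(small_lr, ["a", "b"], rng,
                                     pairs_range=(3, 6))

    @pytest.mark.parametrize("fraction,expected", [(1.0, 4), (0.0, 0)])
    def test_cell_level_fraction_extremes(self, rng, small_lr, fraction,
                                          expected):
        truth = _truth_for(None, {("a", "b"): [0, 1]})
        cells = {0: "a", 1: "b", 2: "a", 3: "b"}
        out = spatial.sample_cell_level_truth(truth, [(0, 1), (2, 3)], cells,
                                              fraction, rng)
        assert len(out) == expected

    def test_cell_level_count_is_exact(self, rng):
        truth = _truth_for(None, {("a", "b"): [0]})
        pairs = [(i, 1000 + i) for i in range(1000)]
        cells = {i: "a" for i in range(1000)}
        cells.update({1000 + i: "b" for i in range(1000)})
        out = spatial.sample_cell_level_truth(truth, pairs, cells, 0.8, rng)
        assert len(out) == 800


class TestLigCif:
    def test_no_neighbors_gives_zero_segment(self, small_lr):
        seg = spatial.build_lig_cif([None] * 4, np.zeros((2, 10)), 0,
                                    lambda c, x: [0, 1], small_lr, 4)
        np.testing.assert_array_equal(seg, 0.0)

    def test_ligand_at_mean_gives_half(self, small_lr):
        # ligand genes are 7 and 8; neighbour expresses both at the same level
        expr = np.zeros((2, 10))
        expr[1, 6] = expr[1, 7] = 4.0
        seg = spatial.build_lig_cif([1, None, None, None], expr, 0,
                                    lambda c, x: [0], small_lr, 4)
        assert seg[0] == pytest.approx(0.5)
        assert seg[1] == 0.0  # row 1 masked

    def test_truth_mask_zeroes_inactive_rows(self, small_lr):
        expr = np.zeros((2, 10))
        expr[1, 6] = expr[1, 7] = 4.0
        seg = spatial.build_lig_cif([1, None, None, None], expr, 0,
                                    lambda c, x: [], small_lr, 4)
        np.testing.assert_array_equal(seg, 0.0)

    def test_effect_matrix_targets_receptor_columns(self, small_lr):
        giv = spatial.lig_effect_giv(small_lr, 10, 4)
        assert giv.shape == (8, 10)
        assert giv[0, 2] == 2.0  # row 0: receptor gene 3
        assert giv[1, 4] == 3.0  # row 1: receptor gene 5
        assert giv.sum() == 4 * (2.0 + 3.0)


@pytest.fixture(scope="module")
def small_run():
    cfg = m.SimConfig(ncell=60, ngene=110, ncif=20,
                      grn=fixtures.build_grn_100(),
                      lr_db=fixtures.build_main_cci(), spatial=True,
                      tc=5, seed=1, population="continuous",
                      tree=m.builtin_tree("Phyla3"))
    return m.simulate(cfg)


class TestRunSpatial:
    def test_single_cell_run(self):
        cfg = m.SimConfig(ncell=1, ngene=110, ncif=10,
                          grn=fixtures.build_grn_100(),
                          lr_db=fixtures.build_main_cci(), spatial=True,
                          tc=0, seed=1, tree=m.builtin_tree("Phyla1"),
                          population="continuous")
        res = m.simulate(cfg)
        assert res.counts.shape == (1, 110)

    def test_all_cells_placed_once(self, small_run):
        state = small_run.spatial_state
        assert len(state.positions) == 60
        assert len(set(state.positions.values())) == 60

    def test_multiple_developmental_stages_present(self, small_run):
        # cells born at different steps sit at different tree positions
        assert len(set(small_run.meta.cell_type)) >= 3
        assert small_run.meta.pseudotime.max() > small_run.meta.pseudotime.min()

    def test_truth_edges_subset_of_neighbour_pairs(self, small_run):
        nb = {(min(i, j), max(i, j))
              for i in range(60)
              for j in spatial.neighbors(small_run.spatial_state, i)}
        for i, j, _ in small_run.cci_truth.cell_level:
            assert (i, j) in nb

    def test_requires_lr_database(self):
        cfg = m.SimConfig(ncell=5, ngene=10, spatial=True, lr_db=None)
        with pytest.raises(ValueError, match="ligand-receptor"):
            m.simulate(cfg)


class TestCorrelationCheck:
    def test_invalid_row_rejected(self, rng):
        cfg = m.SimConfig(ncell=30, ngene=110, ncif=10,
                          grn=fixtures.build_grn_100(),
                          lr_db=fixtures.build_main_cci(), spatial=True,
                          tc=2, seed=4, tree=m.builtin_tree("Phyla1"),
                          population="continuous")
        res = m.simulate(cfg)
        with pytest.raises(ValueError):
            spatial.cci_correlation_check(res, 99, rng)

    def test_shuffled_expression_has_no_correlation(self, rng):
        cfg = m.SimConfig(ncell=100, ngene=110, ncif=10,
                          grn=fixtures.build_grn_100(),
                          lr_db=fixtures.build_main_cci(), spatial=True,
                          tc=2, seed=4, tree=m.builtin_tree("Phyla3"),
                          population="continuous")
        res = m.simulate(cfg)
        res.counts = res.counts[rng.permutation(100)]
        vals = [spatial.cci_correlation_check(res, row, rng) for row in range(5)]
        means = np.nanmean(np.array(vals), axis=0)
        assert np.all(np.abs(means) < 0.15)
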