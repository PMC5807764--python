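"""Cost-distance and categorical corridor classification."""

import numpy as np
import pytest

import oracles
from phylocorridor import (
    ConfigurationError,
    CostRaster,
    InputError,
    SuitabilityRaster,
    cost_distance,
    invert_suitability,
    make_landscape,
    pair_corridor,
    summed_corridor,
)
from phylocorridor.corridor import UnreachablePairError, snap_population_cells


def uniform_cost(n_rows, n_cols, c=1.0, cell_size=1.0):
    return CostRaster(values=np.full((n_rows, n_cols), c), cell_size=cell_size)


class TestInvertSuitability:
    def test_floor_engages_at_full_suitability(self):
        s = SuitabilityRaster(values=np.array([[1.0, 0.0, 0.4]]))
        cost = invert_suitability(s, floor=1e-3)
        np.testing.assert_allclose(cost.values, [[1e-3, 1.0, 0.6]])

    def test_rank_order_reversed(self):
        rng = np.random.default_rng(0)
        vals = rng.random((6, 6))
        s = SuitabilityRaster(values=vals)
        cost = invert_suitability(s)
        order_s = np.argsort(vals.ravel())
        order_c = np.argsort(-cost.values.ravel())
        np.testing.assert_array_equal(order_s, order_c)

    def test_nodata_propagated(self):
        vals = np.array([[0.5, np.nan]])
        cost = invert_suitability(SuitabilityRaster(values=vals))
        assert np.isnan(cost.values[0, 1])

    def test_nonpositive_floor_rejected(self):
        s = SuitabilityRaster(values=np.array([[0.5]]))
        with pytest.raises(ConfigurationError):
            invert_suitability(s, floor=0.0)


class TestCostDistance:
    def test_uniform_straight_line(self):
        cost = uniform_cost(1, 10, c=2.0, cell_size=3.0)
        cd = cost_distance(cost, (0, 0))
        for k in range(10):
            assert cd.values[0, k] == pytest.approx(k * 2.0 * 3.0)

    def test_uniform_diagonal(self):
        cost = uniform_cost(2, 2, c=1.5, cell_size=2.0)
        cd = cost_distance(cost, (0, 0))
        assert cd.values[1, 1] == pytest.approx(1.5 * 2.0 * np.sqrt(2))

    def test_symmetric_in_endpoints(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            cost = CostRaster(values=rng.uniform(0.1, 2.0, size=(5, 5)))
            a, b = (0, 0), (4, 3)
            cd_a = cost_distance(cost, a)
            cd_b = cost_distance(cost, b)
            assert cd_a.values[b] == pytest.approx(cd_b.values[a])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration_4x4(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.05, 3.0, size=(4, 4))
        cost = CostRaster(values=vals)
        oracle = oracles.grid_accumulated_costs(vals)
        for r in range(4):
            for c in range(4):
                cd = cost_distance(cost, (r, c)).values.ravel()
                np.testing.assert_allclose(cd, oracle[r * 4 + c], atol=1e-9)

    def test_nodata_blocks_paths(self):
        vals = np.ones((3, 3))
        vals[:, 1] = np.nan  # vertical barrier
        cost = CostRaster(values=vals)
        cd = cost_distance(cost, (1, 0))
        assert np.isinf(cd.values[1, 2])
        assert np.isnan(cd.values[1, 1])

    def test_nodata_source_rejected(self):
        vals = np.ones((2, 2))
        vals[0, 0] = np.nan
        with pytest.raises(InputError):
            cost_distance(CostRaster(values=vals), (0, 0))


class TestPairCorridor:
    def test_same_cell_class_three_at_cell(self):
        cost = uniform_cost(5, 5)
        classes, c_star = pair_corridor(cost, (2, 2), (2, 2))
        assert c_star == 0.0
        assert classes[2, 2] == 3

    def test_strip_path_is_class_three(self):
        cost = uniform_cost(1, 30)
        classes, c_star = pair_corridor(cost, (0, 0), (0, 29))
        # V is constant (= c*) along the whole strip
        assert (classes == 3).all()

    def test_min_corridor_value_equals_point_to_point_lcp(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0.1, 2.0, size=(6, 8))
        cost = CostRaster(values=vals)
        a, b = (0, 0), (5, 7)
        _, c_star = pair_corridor(cost, a, b)
        assert c_star == pytest.approx(cost_distance(cost, a).values[b])

    def test_classes_nested(self):
        rng = np.random.default_rng(3)
        cost = CostRaster(values=rng.uniform(0.1, 1.0, size=(15, 25)))
        classes, _ = pair_corridor(cost, (7, 0), (7, 24))
        assert set(np.unique(classes)) <= {0, 1, 2, 3}
        for hi, lo in ((3, 2), (2, 1)):
            assert ((classes >= hi) <= (classes >= lo)).all()
            assert (classes >= hi).sum() <= (classes >= lo).sum()

    def test_quantile_mode_invariant_to_cost_scaling(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0.1, 1.0, size=(10, 20))
        a, b = (5, 0), (5, 19)
        c1, _ = pair_corridor(CostRaster(values=vals), a, b)
        c2, _ = pair_corridor(CostRaster(values=vals * 10), a, b)
        np.testing.assert_array_equal(c1, c2)

    def test_unreachable_pair_raises(self):
        vals = np.ones((3, 5))
        vals[:, 2] = np.nan
        with pytest.raises(UnreachablePairError):
            pair_corridor(CostRaster(values=vals), (1, 0), (1, 4))


class TestSummedCorridor:
    def test_single_pair_equals_class_raster(self):
        cost = uniform_cost(8, 12)
        cmap = summed_corridor(cost, [("A", "B")], {"A": (4, 0), "B": (4, 11)})
        classes, _ = pair_corridor(cost, (4, 0), (4, 11))
        np.testing.assert_array_equal(cmap.summed.values, classes.astype(float))

    def test_disjoint_pairs_do_not_superpose(self):
        vals = np.ones((9, 12))
        vals[4, :] = np.nan  # split into two independent strips
        cost = CostRaster(values=vals)
        cmap = summed_corridor(
            cost,
            [("A", "B"), ("C", "D")],
            {"A": (1, 0), "B": (1, 11), "C": (7, 0), "D": (7, 11)},
        )
        assert np.nanmax(cmap.summed.values) == 3

    def test_unreachable_pair_skipped_and_recorded(self):
        vals = np.ones((3, 6))
        vals[:, 3] = np.nan
        cost = CostRaster(values=vals)
        cmap = summed_corridor(
            cost, [("A", "B"), ("A", "C")],
            {"A": (1, 0), "B": (1, 2), "C": (1, 5)},
        )
        assert len(cmap.per_pair) == 1
        assert [(a, b) for a, b, _ in cmap.skipped_pairs] == [("A", "C")]

    def test_empty_pair_list_warns_all_zero(self):
        cost = uniform_cost(4, 4)
        with pytest.warns(UserWarning):
            cmap = summed_corridor(cost, [], {})
        assert np.nansum(cmap.summed.values) == 0

    def test_planted_band_recovery(self, landscape_config):
        raster = make_landscape(landscape_config)
        cost = invert_suitability(raster)
        pops = {f"P{i}": (10, c) for i, c in enumerate((0, 15, 30, 45, 59))}
        pairs = [(a, b) for i, a in enumerate(pops) for b in list(pops)[i + 1 :]]
        cmap = summed_corridor(cost, pairs, pops)
        band = np.zeros(raster.shape, bool)
        band[8:13, :] = True
        max_val = cmap.summed.values.max()
        # band-center cells between the middle populations see every corridor
        assert cmap.summed.values[10, 20:40].max() == max_val
        assert (cmap.summed.values[~band] < max_val).all()


class TestSnapping:
    def test_snaps_to_nearest_defined_cell(self):
        vals = np.ones((4, 4))
        vals[0, 0] = np.nan
        cells = snap_population_cells(CostRaster(values=vals), {"A": (0.5, 3.5)})
        assert cells["A"] in {(0, 1), (1, 0), (1, 1)}

    def test_far_from_defined_cells_rejected(self):
        vals = np.full((5, 5), np.nan)
        vals[4, 4] = 1.0
        with pytest.raises(InputError):
            snap_population_cells(CostRaster(values=vals), {"A": (0.5, 4.5)})
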