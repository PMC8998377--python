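import numpy as np
import pytest

from conftest import brute_force_jenks, make_grid
from landrisk.landscape_metrics import MetricWeights, metric_table
from landrisk.risk_assessment import (
    assess_risk,
    classify_risk,
    grade_area_table,
    jenks_breaks,
    krige_surface,
    landscape_eri,
    make_units,
    unit_eri,
)


class TestMakeUnits:
    def test_exact_tiling(self):
        grid = make_grid(np.ones((30, 30), dtype=int), cell_size=30.0)
        units = make_units(grid, side_km=0.3, min_inside_fraction=0.0)
        assert len(units) == 9
        assert all(u.area_ha == pytest.approx(0.09 * 100) for u in units)

    def test_half_masked_box(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[:, 15:] = True
        grid = make_grid(np.ones((30, 30), dtype=int), mask=mask)
        units = make_units(grid, side_km=0.3, min_inside_fraction=0.5)
        # left column fully inside, middle column exactly at the 0.5
        # threshold (retained), right column fully masked (dropped)
        assert len(units) == 6
        units_strict = make_units(grid, side_km=0.3, min_inside_fraction=0.6)
        assert len(units_strict) == 3

    def test_snapping_to_cells(self):
        grid = make_grid(np.ones((10, 10), dtype=int), cell_size=30.0)
        units = make_units(grid, side_km=0.1, min_inside_fraction=0.0)  # 100 m -> 3 cells
        assert units[0].row_slice.stop - units[0].row_slice.start == 3

    def test_side_smaller_than_cell(self):
        grid = make_grid(np.ones((5, 5), dtype=int), cell_size=30.0)
        with pytest.raises(ValueError):
            make_units(grid, side_km=-1.0)


class TestUnitEri:
    def test_pure_unit_collapses_to_loss_index(self):
        grid = make_grid(np.ones((6, 6), dtype=int))
        units = make_units(grid, side_km=0.18, min_inside_fraction=0.0)
        eri = unit_eri(units[0], {1: 0.42})
        assert eri == pytest.approx(0.42)

    def test_convex_mixture(self):
        v = np.ones((4, 4), dtype=int)
        v[:, 2:] = 2
        grid = make_grid(v)
        units = make_units(grid, side_km=0.12, min_inside_fraction=0.0)
        assert unit_eri(units[0], {1: 0.2, 2: 0.6}) == pytest.approx(0.4)

    def test_missing_loss_raises(self):
        grid = make_grid(np.ones((3, 3), dtype=int))
        units = make_units(grid, side_km=0.09, min_inside_fraction=0.0)
        with pytest.raises(ValueError, match="missing"):
            unit_eri(units[0], {})

    def test_bounded_by_max_loss(self, cma_mini):
        grid, _ = cma_mini
        tab = metric_table(grid)
        loss = tab["R"].to_dict()
        rmax = np.nanmax(list(loss.values()))
        units = make_units(grid, side_km=0.9)
        for u in units:
            assert 0.0 <= unit_eri(u, loss) <= rmax + 1e-12

    def test_two_unit_hand_computation(self):
        # left unit all class 1, right all class 2; per-unit metrics by hand:
        # one square patch each -> C = 1/A_ha, N = 0.5/sqrt(A), F = 1
        v = np.ones((3, 6), dtype=int)
        v[:, 3:] = 2
        grid = make_grid(v, cell_size=100.0, class_table={
            1: {"name": "a", "vulnerability_level": 4},
            2: {"name": "b", "vulnerability_level": 1},
        })
        w = MetricWeights(vulnerability_levels={1: 4, 2: 1})
        units = make_units(grid, side_km=0.3, min_inside_fraction=0.0)
        a_ha = 9.0
        e = 0.5 * (1 / a_ha) + 0.3 * (0.5 / np.sqrt(a_ha)) + 0.2 * 1.0
        for u, rank in zip(units, (4, 1)):
            scope = np.zeros(grid.shape, bool)
            scope[u.row_slice, u.col_slice] = True
            tab = metric_table(grid, w, scope=scope)
            got = unit_eri(u, tab["R"].to_dict())
            assert got == pytest.approx(e * rank / 5.0, rel=1e-12)

    def test_construction_raises_risk(self, cma_mini):
        """With the loss indices held fixed, swapping forest for construction
        strictly raises a unit's ERI whenever R_construction > R_forest."""
        grid, _ = cma_mini
        loss = metric_table(grid)["R"].to_dict()
        assert loss[6] > loss[2]  # construction's loss exceeds forest's here
        units = make_units(grid, side_km=0.9)
        u = max(units, key=lambda u: u.composition_ha[2])
        before = unit_eri(u, loss)
        shifted = dict(u.composition_ha)
        moved = shifted[2] * 0.5
        shifted[2] -= moved
        shifted[6] += moved
        u2 = type(u)(id=u.id, row_slice=u.row_slice, col_slice=u.col_slice,
                     centroid_rc=u.centroid_rc, area_ha=u.area_ha, composition_ha=shifted)
        assert unit_eri(u2, loss) > before


class TestKriging:
    def _units(self, n=16, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.array([(r * 5 + 2, c * 5 + 2) for r in range(4) for c in range(4)], dtype=float)
        return pts, rng

    def test_constant_field(self):
        pts, _ = self._units()
        vals = np.full(len(pts), 3.7)
        field = krige_surface(pts, vals, (20, 20))
        assert np.allclose(field, 3.7, atol=1e-8)

    def test_exact_at_samples_with_zero_nugget(self):
        pts, rng = self._units()
        vals = rng.random(len(pts))
        field = krige_surface(pts, vals, (20, 20), nugget=0.0)
        for (r, c), v in zip(pts.astype(int), vals):
            assert field[r, c] == pytest.approx(v, abs=1e-6)

    def test_linear_trend_monotone(self):
        pts, _ = self._units()
        vals = pts[:, 0] * 0.1
        field = krige_surface(pts, vals, (20, 20))
        col = field[2:18, 10]
        assert np.all(np.diff(col) > -1e-6)

    def test_duplicate_points_rejected(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="duplicate"):
            krige_surface(pts, np.array([1.0, 2.0, 3.0]), (5, 5))


class TestJenks:
    def test_five_distinct_values(self):
        bp = jenks_breaks(np.array([1, 2, 3, 4, 5], dtype=float), 5)
        assert list(bp) == [1, 2, 3, 4]

    def test_two_clusters(self):
        vals = np.array([1.0, 1.1, 1.2, 9.0, 9.1, 9.3])
        bp = jenks_breaks(vals, 2)
        assert bp[0] == pytest.approx(1.2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 21)
        k = rng.integers(2, 5)
        vals = rng.random(n) * 10
        bp = jenks_breaks(vals, k)
        _, grades = classify_risk(vals, k, breakpoints=bp)
        x = np.sort(vals)
        got_sse = sum(
            float(((x[(x > lo) & (x <= hi)] - x[(x > lo) & (x <= hi)].mean()) ** 2).sum())
            for lo, hi in zip([-np.inf, *bp], [*bp, np.inf])
            if ((x > lo) & (x <= hi)).any()
        )
        best_sse, _ = brute_force_jenks(vals, k)
        assert got_sse == pytest.approx(best_sse, abs=1e-9)

    def test_too_few_distinct(self):
        with pytest.raises(ValueError):
            jenks_breaks(np.array([1.0, 1.0, 2.0]), 3)

    def test_order_independent(self):
        vals = np.array([5.0, 1.0, 9.0, 2.0, 7.0, 3.0, 8.0])
        assert np.array_equal(jenks_breaks(vals, 3), jenks_breaks(vals[::-1], 3))


class TestGradeAreas:
    def test_identical_maps_zero_delta(self):
        gm = np.random.default_rng(0).integers(1, 6, size=(10, 10))
        tab = grade_area_table({"a": gm, "b": gm.copy()}, cell_area_km2=0.0009)
        assert np.allclose(tab.loc["a->b"], 0.0)

    def test_single_cell_recode(self):
        gm = np.ones((4, 4), dtype=int)
        gm2 = gm.copy()
        gm2[0, 0] = 5
        tab = grade_area_table({"a": gm, "b": gm2}, cell_area_km2=0.0009)
        assert tab.loc["a->b", "grade_1"] == pytest.approx(-0.0009)
        assert tab.loc["a->b", "grade_5"] == pytest.approx(0.0009)
        assert tab.loc["a->b"].sum() == pytest.approx(0.0)

    def test_deltas_match_counting(self, cma_mini):
        grid, _ = cma_mini
        s = assess_risk(grid, side_km=0.9)
        counts = {g: int((s.grade_map == g).sum()) for g in range(1, 6)}
        tab = grade_area_table({"x": s.grade_map}, grid.cell_area_km2)
        for g in range(1, 6):
            assert tab.loc["x", f"grade_{g}"] == pytest.approx(counts[g] * grid.cell_area_km2)


class TestAssessRisk:
    def test_pipeline_outputs(self, cma_mini):
        grid, _ = cma_mini
        s = assess_risk(grid, side_km=0.9)
        assert len(s.units) == 49
        assert s.interpolated_field.shape == grid.shape
        assert s.grade_map.max() <= 5 and s.grade_map[~grid.nodata_mask].min() >= 1
        assert len(s.breakpoints) == 4
        # grade areas cover the landscape
        total = sum((s.grade_map == g).sum() for g in range(1, 6))
        assert total == grid.n_unmasked

    def test_landscape_scope_invariant_to_tiling(self, cma_mini):
        grid, _ = cma_mini
        w = MetricWeights()
        whole = landscape_eri(grid, w)
        s = assess_risk(grid, w, side_km=6.0, min_inside_fraction=0.0, metric_scope="landscape", krige=False)
        assert len(s.units) == 1
        assert s.unit_values[0] == pytest.approx(whole)

    def test_frozen_breakpoints_respected(self, cma_mini):
        grid, _ = cma_mini
        bp = np.array([0.0761, 0.0906, 0.1093, 0.1315])
        s = assess_risk(grid, side_km=0.9, breakpoints=bp)
        assert np.array_equal(s.breakpoints, bp)
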