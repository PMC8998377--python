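import numpy as np
import pandas as pd
import pytest

from conftest import make_grid
from landrisk.cars import (
    CAState,
    ConvergenceError,
    TransitionMatrix,
    inertia_coefficient,
    neighborhood_effect,
    overall_probability,
    simulate,
)
from landrisk.grid_io import crosstab_change
from landrisk.leas import GrowthProbability


def uniform_growth(grid, classes, value=0.5):
    return GrowthProbability(
        prob={k: np.full(grid.shape, value) for k in classes},
        importances={k: {} for k in classes},
        oob_score={k: float("nan") for k in classes},
    )


class TestNeighborhood:
    def test_uniform_interior(self):
        grid = make_grid(np.full((5, 5), 2))
        om = neighborhood_effect(grid, 2, window=3, weight=1.0)
        assert om[2, 2] == pytest.approx(1.0)
        assert om[0, 0] == pytest.approx(3 / 8)  # corner: 3 of 8 neighbors exist

    def test_isolated_cell_neighbors(self):
        v = np.ones((5, 5), dtype=int)
        v[2, 2] = 2
        grid = make_grid(v)
        om = neighborhood_effect(grid, 2, window=3, weight=1.0)
        assert om[2, 2] == 0.0  # own window excludes the center
        assert om[2, 1] == pytest.approx(1 / 8)
        assert om[1, 1] == pytest.approx(1 / 8)

    def test_zero_weight(self):
        grid = make_grid(np.full((4, 4), 2))
        assert not neighborhood_effect(grid, 2, weight=0.0).any()

    def test_bad_window(self):
        grid = make_grid(np.full((4, 4), 2))
        with pytest.raises(ValueError):
            neighborhood_effect(grid, 2, window=4)


class TestInertia:
    def test_equilibrium(self):
        assert inertia_coefficient(5.0, 0.0, 10.0, tol_cells=1.0) == 1.0

    def test_shrinking_gap_resets(self):
        assert inertia_coefficient(3.0, 5.0, 8.0, tol_cells=1.0) == 1.0

    def test_undersupply_widening_increases(self):
        d0 = 1.0
        d1 = inertia_coefficient(d0, gap=20.0, prev_gap=10.0, tol_cells=1.0)
        assert d1 > d0

    def test_oversupply_widening_decreases(self):
        d0 = 1.0
        d1 = inertia_coefficient(d0, gap=-20.0, prev_gap=-10.0, tol_cells=1.0)
        assert 0 < d1 < d0


class TestOverallProbability:
    def test_branch2_product(self):
        rng = np.random.default_rng(0)
        op = overall_probability(np.array([[0.8]]), np.array([[0.5]]), 1.0, 0.1, rng)
        assert op[0, 0] == pytest.approx(0.4)

    def test_zero_threshold_no_seeding(self):
        rng = np.random.default_rng(0)
        op = overall_probability(np.full((50, 50), 0.9), np.zeros((50, 50)), 1.0, 0.0, rng)
        assert not op.any()

    def test_seeding_frequency_matches_bernoulli(self):
        """With Omega=0 the seeding branch fires iff r < P: frequency -> P."""
        rng = np.random.default_rng(42)
        n = 100_000
        P = np.full((n,), 0.6)
        op = overall_probability(P, np.zeros(n), 1.0, 1.0, rng)
        freq = (op > 0).mean()
        assert freq == pytest.approx(0.6, abs=3 * np.sqrt(0.6 * 0.4 / n))


class TestTransitionMatrix:
    def test_diagonal_enforced(self):
        with pytest.raises(ValueError):
            TransitionMatrix(classes=[1, 2], allowed=np.array([[0, 1], [1, 1]]))

    def test_forbid(self):
        tm = TransitionMatrix.all_allowed([1, 2])
        tm.forbid(1, 2)
        assert not tm.is_allowed(1, 2)
        assert tm.is_allowed(2, 1)


class TestSimulate:
    def _toy(self, seed=0, shape=(40, 40)):
        rng = np.random.default_rng(seed)
        v = np.where(rng.random(shape) < 0.8, 2, 6)
        ct = {2: {"name": "forest", "vulnerability_level": 2},
              6: {"name": "construction", "vulnerability_level": 1}}
        return make_grid(v, class_table=ct)

    def test_demand_equals_current_is_identity(self):
        grid = self._toy()
        demand = grid.class_areas_ha()
        growth = uniform_growth(grid, [2, 6])
        out, audit = simulate(grid, growth, CAState(demand_ha=demand, seed=1))
        assert np.array_equal(out.values, grid.values)
        assert len(audit) == 0

    def test_directed_shift_all_allowed_transitions(self):
        """Demand moves 100 cells 2 -> 6 with only that conversion allowed."""
        grid = self._toy(seed=3)
        areas = grid.class_areas_ha()
        shift = 100 * grid.cell_area_ha
        demand = {2: areas[2] - shift, 6: areas[6] + shift}
        tm = TransitionMatrix(classes=[2, 6], allowed=np.array([[1, 1], [0, 1]]))
        growth = uniform_growth(grid, [2, 6])
        state = CAState(demand_ha=demand, seed=7, demand_tolerance=0.0)
        out, audit = simulate(grid, growth, state, tm=tm)
        ct = crosstab_change(grid, out)
        assert ct.loc[6, 2] == 0.0
        assert ct.loc[2, 6] == pytest.approx(shift / 100.0)
        assert out.class_counts()[6] == grid.class_counts()[6] + 100

    def test_area_conserved_every_iteration(self):
        grid = self._toy(seed=5)
        areas = grid.class_areas_ha()
        shift = 150 * grid.cell_area_ha
        demand = {2: areas[2] - shift, 6: areas[6] + shift}
        growth = uniform_growth(grid, [2, 6])
        out, audit = simulate(grid, growth, CAState(demand_ha=demand, seed=2))
        # gap_2 + gap_6 must cancel at every logged iteration
        assert (audit["gap_2"] + audit["gap_6"]).abs().max() == 0

    def test_restricted_cells_untouched(self):
        grid = self._toy(seed=8)
        areas = grid.class_areas_ha()
        shift = 80 * grid.cell_area_ha
        demand = {2: areas[2] - shift, 6: areas[6] + shift}
        restricted = np.zeros(grid.shape, dtype=bool)
        restricted[:10, :] = True
        growth = uniform_growth(grid, [2, 6])
        out, _ = simulate(grid, growth, CAState(demand_ha=demand, seed=2), restricted_mask=restricted)
        assert np.array_equal(out.values[restricted], grid.values[restricted])

    def test_seed_reproducibility_and_variation(self):
        grid = self._toy(seed=9)
        areas = grid.class_areas_ha()
        shift = 120 * grid.cell_area_ha
        demand = {2: areas[2] - shift, 6: areas[6] + shift}
        growth = uniform_growth(grid, [2, 6])
        outs = [simulate(grid, growth, CAState(demand_ha=demand, seed=s))[0] for s in (4, 4, 5)]
        assert np.array_equal(outs[0].values, outs[1].values)
        assert not np.array_equal(outs[0].values, outs[2].values)
        # different seeds still satisfy the same demand
        assert outs[0].class_counts() == outs[2].class_counts()

    def test_infeasible_demand_rejected(self):
        grid = self._toy()
        growth = uniform_growth(grid, [2, 6])
        with pytest.raises(ValueError, match="infeasible"):
            simulate(grid, growth, CAState(demand_ha={2: 1.0, 6: 1.0}, seed=0))

    def test_nonconvergence_reports_residual(self):
        grid = self._toy(seed=10)
        areas = grid.class_areas_ha()
        shift = 100 * grid.cell_area_ha
        demand = {2: areas[2] - shift, 6: areas[6] + shift}
        # zero growth probability for the needed class: nothing can be placed
        growth = uniform_growth(grid, [2, 6], value=0.0)
        state = CAState(demand_ha=demand, seed=0, max_iterations=5)
        with pytest.raises(ConvergenceError) as err:
            simulate(grid, growth, state)
        assert err.value.residual_gaps[6] == pytest.approx(shift)

    def test_threshold_descent_decays_when_stalled(self):
        """On a run that makes no progress, the decay counter increments every
        iteration, so the logged tau base decays geometrically."""
        grid = self._toy(seed=10)
        areas = grid.class_areas_ha()
        shift = 100 * grid.cell_area_ha
        demand = {2: areas[2] - shift, 6: areas[6] + shift}
        growth = uniform_growth(grid, [2, 6], value=0.0)
        delta = 0.5
        with pytest.raises(ConvergenceError) as err:
            simulate(grid, growth, CAState(demand_ha=demand, seed=0, max_iterations=6, decay_factor=delta))
        trace = err.value.audit["tau_base"].to_numpy()
        assert np.allclose(trace, delta ** np.arange(1, len(trace) + 1))

    def test_patch_seeding_increases_patch_count(self, cma_mini_pair):
        """With mu > 0 and dispersed growth probability, an expanding class
        gains patches (the patch-generating mechanism)."""
        from landrisk.grid_io import extract_patches

        g1, g2, drivers, *_ = cma_mini_pair
        rng_success = 0
        n_rep = 10
        for s in range(n_rep):
            grid = g2
            areas = grid.class_areas_ha()
            shift = 200 * grid.cell_area_ha
            demand = dict(areas)
            demand[6] += shift
            demand[2] -= shift
            rng = np.random.default_rng(100 + s)
            dispersed = rng.random(grid.shape)  # spatially uncorrelated growth preference
            growth = GrowthProbability(prob={k: (dispersed if k == 6 else np.zeros(grid.shape))
                                             for k in grid.class_codes()},
                                       importances={}, oob_score={})
            out, _ = simulate(grid, growth, CAState(demand_ha=demand, seed=100 + s, patch_threshold=0.5))
            before = extract_patches(grid).n[6]
            after = extract_patches(out).n[6]
            if after > before:
                rng_success += 1
        assert rng_success >= 0.9 * n_rep
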