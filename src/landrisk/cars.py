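"""Cellular automaton with multi-type random patch seeds and threshold descent.

Each iteration combines, per cell i and class k, the learned development
probability P_{i,k}, the neighborhood effect Omega_{i,k} (weighted cover
ratio of k in the moving window), and a self-adaptive inertia D_k^t driven
by the gap between current area and demand:

    OP_{i,k} = P_{i,k} * (r * mu_k) * D_k   if Omega_{i,k} = 0 and r < P_{i,k}
    OP_{i,k} = P_{i,k} * Omega_{i,k} * D_k  otherwise

with r ~ U(0,1) per cell/class. The first branch is the Monte-Carlo patch
*seeding* mechanism: a class with no presence in the window can still
spawn a new patch with probability controlled by the seeding threshold
mu_k. A candidate class c is then drawn per cell by roulette wheel over OP,
and the conversion happens only if P_{i,c} exceeds the decaying threshold
tau = delta**d * r1 (r1 ~ U(0.9, 1.1), mean 1) and the binary transition
matrix allows current -> c. The decay counter d increments whenever an
iteration improves the total absolute demand gap by less than ``step``, so
a stalling simulation progressively lowers the bar until residual demand
can be placed.

Conversions are balanced against demand each iteration: a cell converts
only from an over-supplied class to an under-supplied one, and per-class
acceptance is capped at the remaining gap, so total area is conserved
exactly and the run terminates when every class is within tolerance of its
demand.

The inertia coefficient is only verbally characterized in the PLUS
literature; here it is the capped gap-ratio rule: D resets to 1 when the
gap closes or shrinks, is multiplied by |G_{t-1}/G_t| (capped at 2 per
step, floored at 0.01) when an under-supplied gap widens, and divided
likewise when an over-supplied gap widens. Every iteration's D, tau and
gaps are written to the audit log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from landrisk.grid_io import LandUseGrid
from landrisk.leas import GrowthProbability

logger = logging.getLogger(__name__)

#: Neighborhood weights (expansion strength, 0-1) for the six-class scheme:
#: construction 1, forest 0.8, cultivated and grassland 0.5, orchard 0.5
#: (between cultivated and forest), water 0.1.
DEFAULT_NEIGHBORHOOD_WEIGHTS = {1: 0.5, 2: 0.8, 3: 0.5, 4: 0.5, 5: 0.1, 6: 1.0}


@dataclass
class TransitionMatrix:
    """Binary permission table for class-to-class conversion (diagonal = 1)."""

    classes: list[int]
    allowed: np.ndarray  # (K, K) of {0,1}, rows = from, cols = to

    def __post_init__(self) -> None:
        self.allowed = np.asarray(self.allowed, dtype=np.int8)
        K = len(self.classes)
        if self.allowed.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if not np.all(np.diag(self.allowed) == 1):
            raise ValueError("transition matrix diagonal must be 1 (a class may keep itself)")

    @classmethod
    def all_allowed(cls, classes: list[int]) -> "TransitionMatrix":
        return cls(classes=list(classes), allowed=np.ones((len(classes), len(classes)), dtype=np.int8))

    def copy(self) -> "TransitionMatrix":
        return TransitionMatrix(classes=list(self.classes), allowed=self.allowed.copy())

    def is_allowed(self, from_code: int, to_code: int) -> bool:
        i = self.classes.index(from_code)
        j = self.classes.index(to_code)
        return bool(self.allowed[i, j])

    def forbid(self, from_code: int, to_code: int) -> None:
        if from_code == to_code:
            raise ValueError("cannot forbid a class keeping itself")
        self.allowed[self.classes.index(from_code), self.classes.index(to_code)] = 0


@dataclass
class CAState:
    """Tunable parameters of one simulation run."""

    demand_ha: dict[int, float]
    neighborhood_weights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_NEIGHBORHOOD_WEIGHTS))
    window: int = 3
    decay_factor: float = 0.5            # delta in the threshold-descent rule
    patch_threshold: dict[int, float] | float = 0.1   # mu_k, seeding threshold
    step_fraction: float = 0.001         # "step": min gap improvement, fraction of cells
    demand_tolerance: float = 0.001      # stop when every |gap| <= tol * cells
    max_iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay_factor <= 1.0:
            raise ValueError("decay_factor must be in [0, 1]")
        for w in self.neighborhood_weights.values():
            if not 0.0 <= w <= 1.0:
                raise ValueError("neighborhood weights must be in [0, 1]")


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual_gaps: dict[int, float], audit: pd.DataFrame | None = None):
        super().__init__(message)
        self.residual_gaps = residual_gaps
        self.audit = audit


def neighborhood_effect(grid: LandUseGrid, class_code: int, window: int = 3, weight: float = 1.0) -> np.ndarray:
    """Omega: weighted cover ratio of ``class_code`` in each cell's window.

    Omega = (count of k in the window excluding the center) / (window² - 1)
    × weight, hence in [0, weight]. Cells beyond the raster edge count as
    non-k (zero-padded window).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    member = ((grid.values == class_code) & ~grid.nodata_mask).astype(np.float64)
    counts = ndimage.uniform_filter(member, size=window, mode="constant", cval=0.0) * window**2
    counts = np.rint(counts) - member
    return counts / (window**2 - 1) * weight


def inertia_coefficient(
    prev_d: float, gap: float, prev_gap: float | None, tol_cells: float, cap: float = 2.0, floor: float = 0.01
) -> float:
    """Self-adaptive inertia update for one class (see module docstring)."""
    if abs(gap) <= tol_cells or prev_gap is None:
        return 1.0
    if abs(gap) <= abs(prev_gap):
        return 1.0
    ratio = min(cap, max(1.0, abs(prev_gap) / max(abs(gap), 1e-9)) if prev_gap != 0 else 1.0)
    ratio = min(cap, max(ratio, abs(gap) / max(abs(prev_gap), 1e-9)))
    if gap > 0:  # under-supplied and widening: push harder
        return min(prev_d * ratio, 100.0)
    return max(prev_d / ratio, floor)  # over-supplied: damp


def overall_probability(
    P: np.ndarray, omega: np.ndarray, inertia: float, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell overall probability with the Monte-Carlo seeding branch."""
    r = rng.random(P.shape)
    seeding = (omega == 0) & (r < P)
    op = np.where(seeding, P * (r * mu) * inertia, P * omega * inertia)
    return op


def _demand_to_cells(demand_ha: dict[int, float], grid: LandUseGrid) -> dict[int, int]:
    cells_total = grid.n_unmasked
    per_ha = grid.cell_area_ha
    raw = {k: v / per_ha for k, v in demand_ha.items()}
    if abs(sum(raw.values()) - cells_total) > 0.01 * cells_total:
        raise ValueError(
            f"infeasible demand: totals {sum(demand_ha.values()):.1f} ha vs landscape {cells_total * per_ha:.1f} ha"
        )
    cells = {k: int(round(v)) for k, v in raw.items()}
    drift = cells_total - sum(cells.values())
    largest = max(cells, key=cells.get)
    cells[largest] += drift
    return cells


def simulate(
    grid: LandUseGrid,
    growth: GrowthProbability,
    state: CAState,
    tm: TransitionMatrix | None = None,
    restricted_mask: np.ndarray | None = None,
) -> tuple[LandUseGrid, pd.DataFrame]:
    """Run the CA until per-class areas meet demand within tolerance.

    Returns the final grid and a per-iteration audit log (gaps, inertia,
    tau, conversions). Raises :class:`ConvergenceError` with the residual
    gaps when ``max_iterations`` is exhausted.
    """
    classes = grid.class_codes()
    if tm is None:
        tm = TransitionMatrix.all_allowed(classes)
    if list(tm.classes) != classes:
        raise ValueError("transition matrix classes do not match grid")
    if restricted_mask is None:
        restricted_mask = np.zeros(grid.shape, dtype=bool)
    restricted_mask = np.asarray(restricted_mask, dtype=bool)
    rng = np.random.default_rng(state.seed)
    values = grid.values.copy()
    unmasked = ~grid.nodata_mask
    active = unmasked & ~restricted_mask
    demand_cells = _demand_to_cells(state.demand_ha, grid)
    mu = state.patch_threshold
    mu_map = {k: (mu[k] if isinstance(mu, dict) else float(mu)) for k in classes}
    tol_cells = max(1.0, state.demand_tolerance * grid.n_unmasked)
    step_cells = max(1.0, state.step_fraction * grid.n_unmasked)
    cls_index = {k: i for i, k in enumerate(classes)}

    def gaps_now() -> dict[int, int]:
        vals = values[unmasked]
        return {k: demand_cells[k] - int((vals == k).sum()) for k in classes}

    orig_idx_flat = np.searchsorted(classes, grid.values.ravel())
    D = {k: 1.0 for k in classes}
    prev_gaps: dict[int, int] | None = None
    d_counter = 0
    log_rows = []
    gaps = gaps_now()
    prev_total = sum(abs(g) for g in gaps.values())
    converged = all(abs(g) <= tol_cells for g in gaps.values())
    t = 0
    while not converged and t < state.max_iterations:
        t += 1
        for k in classes:
            D[k] = inertia_coefficient(D[k], gaps[k], None if prev_gaps is None else prev_gaps[k], tol_cells)
        work = grid.copy_with(values)
        K = len(classes)
        op = np.zeros((K,) + grid.shape)
        P_of = {}
        for i, k in enumerate(classes):
            P = growth.prob.get(k)
            if P is None:
                P = np.zeros(grid.shape)
            P_of[k] = P
            omega = neighborhood_effect(work, k, window=state.window, weight=state.neighborhood_weights.get(k, 0.5))
            op[i] = overall_probability(P, omega, D[k], mu_map[k], rng)
        op[:, ~active] = 0.0
        # roulette-wheel candidate class per cell
        totals = op.sum(axis=0)
        eligible = active & (totals > 0)
        cand = np.full(grid.shape, -1, dtype=np.int32)
        if eligible.any():
            cum = np.cumsum(op[:, eligible], axis=0)
            draw = rng.random(cum.shape[1]) * cum[-1]
            cand[eligible] = np.argmax(cum > draw[None, :], axis=0)
        # threshold-descent change test
        tau = state.decay_factor**d_counter * rng.uniform(0.9, 1.1, size=grid.shape)
        flat = np.flatnonzero(cand.ravel() >= 0)
        changes = 0
        if len(flat) > 0:
            to_idx = cand.ravel()[flat]
            from_codes = values.ravel()[flat]
            from_idx = np.array([cls_index[c] for c in classes])[np.searchsorted(classes, from_codes)]
            p_c = np.array([P_of[classes[j]].ravel()[f] for j, f in zip(to_idx, flat)])
            op_c = op.reshape(K, -1)[to_idx, flat]
            # gate on both the current class and the cell's original class, so
            # chained conversions cannot realize a forbidden input->output pair
            ok = (
                (to_idx != from_idx)
                & (p_c > tau.ravel()[flat])
                & (tm.allowed[from_idx, to_idx] == 1)
                & (tm.allowed[orig_idx_flat[flat], to_idx] == 1)
            )
            flat, to_idx, from_idx, op_c = flat[ok], to_idx[ok], from_idx[ok], op_c[ok]
            # demand balancing: donors over-supplied, receivers under-supplied
            order = np.argsort(-op_c)
            remaining_need = {k: max(0, gaps[k]) for k in classes}
            remaining_surplus = {k: max(0, -gaps[k]) for k in classes}
            total_need = sum(remaining_need.values())
            new_vals = values.ravel()
            for idx in order:
                if total_need == 0:
                    break
                k_to = classes[to_idx[idx]]
                k_from = classes[from_idx[idx]]
                if remaining_need[k_to] > 0 and remaining_surplus[k_from] > 0:
                    new_vals[flat[idx]] = k_to
                    remaining_need[k_to] -= 1
                    remaining_surplus[k_from] -= 1
                    total_need -= 1
                    changes += 1
            values = new_vals.reshape(grid.shape)
        prev_gaps = gaps
        gaps = gaps_now()
        total = sum(abs(g) for g in gaps.values())
        if prev_total - total < step_cells:
            d_counter += 1
        log_rows.append(
            {
                "iteration": t,
                "d": d_counter,
                "tau_base": state.decay_factor**d_counter,
                "changes": changes,
                "total_abs_gap_cells": total,
                **{f"gap_{k}": gaps[k] for k in classes},
                **{f"D_{k}": D[k] for k in classes},
            }
        )
        prev_total = total
        converged = all(abs(g) <= tol_cells for g in gaps.values())
    audit = pd.DataFrame(log_rows)
    if not converged:
        residual = {k: gaps[k] * grid.cell_area_ha for k in classes}
        raise ConvergenceError(
            f"demand not met after {state.max_iterations} iterations; residual gaps (ha): {residual}",
            residual,
            audit,
        )
    out = grid.copy_with(values, epoch_label=f"{grid.epoch_label}+sim")
    assert np.array_equal(out.values[restricted_mask], grid.values[restricted_mask])
    return out, audit
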