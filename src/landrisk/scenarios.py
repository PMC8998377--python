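"""SDG-oriented scenario encodings and Markov demand projection.

Three built-in scenarios mirror the usual sustainable-development framings:

* **NDS** (natural development): no constraints, demand extrapolates the
  observed trend.
* **EDS** (economic development, SDG 9/12): the probability of converting
  cultivated, orchard, forest, grassland and water into construction land
  is increased by 40%.
* **EPS** (ecological protection, SDG 15): forest-out conversions (to
  cultivated, orchard, water, grassland, construction) reduced by 50%;
  grassland/orchard/water into forest increased by 30%; cultivated,
  orchard, grassland and water into construction reduced by 20%; rivers
  and lakes become restricted areas where no change is allowed.

Multipliers act on the learned growth-probability surfaces (clipped back to
[0, 1]) and, by default, also on the off-diagonal rates of the Markov
demand chain, so demand and allocation shift consistently. When several
rules target the same (from, to) pair the most specific wins by default
(a pairwise rule beats a class-wide rule); ``compose="all"`` multiplies
them instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from landrisk.cars import TransitionMatrix
from landrisk.grid_io import LandUseGrid, crosstab_change
from landrisk.leas import GrowthProbability

#: name -> code for the default six-class scheme.
NAME_TO_CODE = {"cultivated": 1, "forest": 2, "orchard": 3, "grassland": 4, "water": 5, "construction": 6}


@dataclass
class ScenarioSpec:
    """One scenario: conversion-probability multipliers and restrictions.

    ``multipliers`` maps (from_code, to_code) -> factor; ``None`` on either
    side is a wildcard (class-wide rule). ``restricted_classes`` lists codes
    whose cells become a no-change mask (e.g. water under protection).
    """

    name: str
    multipliers: dict[tuple[int | None, int | None], float] = field(default_factory=dict)
    restricted_classes: list[int] = field(default_factory=list)
    demand_mode: str = "markov"
    horizon_label: str = ""

    def __post_init__(self) -> None:
        for pair, f in self.multipliers.items():
            if f <= 0:
                raise ValueError(f"multiplier for {pair} must be > 0")

    def factor(self, from_code: int, to_code: int, compose: str = "specific") -> float:
        """Resolved multiplier for one conversion."""
        exact = self.multipliers.get((from_code, to_code))
        from_wide = self.multipliers.get((from_code, None))
        to_wide = self.multipliers.get((None, to_code))
        if compose == "all":
            f = 1.0
            for m in (exact, from_wide, to_wide):
                if m is not None:
                    f *= m
            return f
        if exact is not None:
            return exact
        # a pairwise rule beats class-wide; among class-wide rules compose
        f = 1.0
        for m in (from_wide, to_wide):
            if m is not None:
                f *= m
        return f


def nds() -> ScenarioSpec:
    """Natural development: pass-through, trend-following demand."""
    return ScenarioSpec(name="NDS")


def eds() -> ScenarioSpec:
    """Economic development: +40% conversion into construction land."""
    c = NAME_TO_CODE
    mult = {(c[f], c["construction"]): 1.4 for f in ("cultivated", "orchard", "forest", "grassland", "water")}
    return ScenarioSpec(name="EDS", multipliers=mult)


def eps() -> ScenarioSpec:
    """Ecological protection: guard forest, restrain construction, restrict water."""
    c = NAME_TO_CODE
    mult: dict[tuple[int | None, int | None], float] = {}
    for to in ("cultivated", "orchard", "water", "grassland", "construction"):
        mult[(c["forest"], c[to])] = 0.5
    for f in ("grassland", "orchard", "water"):
        mult[(c[f], c["forest"])] = 1.3
    for f in ("cultivated", "orchard", "grassland", "water"):
        mult[(c[f], c["construction"])] = 0.8
    return ScenarioSpec(name="EPS", multipliers=mult, restricted_classes=[c["water"]])


BUILTIN_SCENARIOS = {"NDS": nds, "EDS": eds, "EPS": eps}


# ---------------------------------------------------------------------------
# Demand projection
# ---------------------------------------------------------------------------

def transition_rates(epoch1: LandUseGrid, epoch2: LandUseGrid) -> tuple[list[int], np.ndarray]:
    """Row-stochastic class transition-rate matrix estimated from two epochs."""
    ct = crosstab_change(epoch1, epoch2)
    classes = [int(c) for c in ct.index]
    mat = ct.to_numpy()
    rows = mat.sum(axis=1, keepdims=True)
    P = np.divide(mat, rows, out=np.zeros_like(mat), where=rows > 0)
    # a class absent in epoch1 keeps itself
    for i in range(len(classes)):
        if rows[i, 0] == 0:
            P[i, i] = 1.0
    return classes, P


def markov_demand(
    epoch1: LandUseGrid,
    epoch2: LandUseGrid,
    steps: int = 1,
    scenario: ScenarioSpec | None = None,
    compose: str = "specific",
) -> dict[int, float]:
    """Project per-class areas (ha) one or more intervals ahead.

    The transition-rate matrix of the observed interval is applied ``steps``
    times to the later epoch's areas. Under a scenario, its off-diagonal
    rates receive the scenario's conversion multipliers before rows are
    renormalized (diagonal absorbs the slack), shifting demand the same way
    the allocation probabilities shift. Total area is conserved exactly.
    """
    classes, P = transition_rates(epoch1, epoch2)
    if scenario is not None and scenario.multipliers:
        P = P.copy()
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                if i != j:
                    P[i, j] *= scenario.factor(ci, cj, compose=compose)
            off = P[i].sum() - P[i, i]
            if off >= 1.0:  # rescale off-diagonal mass so the row stays stochastic
                P[i] = np.where(np.arange(len(classes)) == i, 0.0, P[i] / off * 0.999)
            P[i, i] = 1.0 - (P[i].sum() - P[i, i])
    areas = np.array([epoch2.class_areas_ha()[c] for c in classes])
    out = areas.copy()
    for _ in range(steps):
        out = out @ P
    return dict(zip(classes, out.tolist()))


def apply_scenario(
    growth: GrowthProbability,
    tm: TransitionMatrix,
    spec: ScenarioSpec,
    grid: LandUseGrid,
    compose: str = "specific",
) -> tuple[GrowthProbability, TransitionMatrix, np.ndarray]:
    """Apply a scenario to growth surfaces, transition matrix and mask.

    Each targeted conversion's probability is multiplied then clipped to
    [0, 1]. Because the growth surface P_{i,k} is per *receiving* class but
    the multiplier may depend on the cell's current (donor) class, the
    factor is applied cell-wise using the current land-use map. NDS returns
    the inputs unchanged (fresh copies).
    """
    for (f, t) in spec.multipliers:
        for code in (f, t):
            if code is not None and code not in grid.class_table:
                raise ValueError(f"scenario {spec.name}: unknown class code {code}")
    new_growth = growth.copy()
    new_tm = tm.copy()
    restricted = np.zeros(grid.shape, dtype=bool)
    for code in spec.restricted_classes:
        if code not in grid.class_table:
            raise ValueError(f"scenario {spec.name}: unknown restricted class {code}")
        restricted |= (grid.values == code) & ~grid.nodata_mask
    if not spec.multipliers:
        return new_growth, new_tm, restricted
    for to_code, surface in new_growth.prob.items():
        factor_map = np.ones(grid.shape)
        for from_code in grid.class_codes():
            if from_code == to_code:
                continue
            f = spec.factor(from_code, to_code, compose=compose)
            if f != 1.0:
                factor_map[grid.values == from_code] = f
        new_growth.prob[to_code] = np.clip(surface * factor_map, 0.0, 1.0)
    return new_growth, new_tm, restricted
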