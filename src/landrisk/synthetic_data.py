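"""Synthetic patch-structured landscapes with drivers and programmed change.

The generator emulates the statistical structure the analysis assumes: a
categorical land-use map built by seeded region growing (so per-class patch
size distributions are directly controllable — a landscape dominated by a
few huge forest patches next to hundreds of small construction patches),
smooth correlated driver surfaces plus distance-to-feature layers, and a
second epoch produced by conversion rules that are logistic in named
drivers, recording the ground truth every downstream stage is tested
against.

The default fixture ("CMA-mini") is a 200 x 200 grid of 30 m cells
(36 km²) with class budgets proportional to the Hainan CMA's year-2000
class areas: forest ~74%, orchard ~10%, cultivated ~8%, grassland ~6%,
water ~0.7%, construction ~0.4%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from landrisk.grid_io import DEFAULT_CLASS_TABLE, DriverStack, LandUseGrid

#: Class-area shares matching the published 2000 CMA composition.
CMA_SHARES = {1: 0.0842, 2: 0.7398, 3: 0.1031, 4: 0.0619, 5: 0.0070, 6: 0.0040}

#: Approximate mean patch size (cells) per class; forest patches two orders
#: of magnitude larger than construction, mirroring the published contrast.
DEFAULT_PATCH_SCALE = {1: 60, 2: 4000, 3: 150, 4: 40, 5: 25, 6: 12}

DRIVER_NAMES = ["elevation", "slope", "dist_road", "dist_river", "dist_town", "population", "gdp"]


@dataclass
class ChangeRule:
    """One programmed conversion: from -> to, logistic in a named driver.

    ``effect`` is the logistic slope on the z-scored driver; negative means
    conversion concentrates where the driver is low (e.g. near towns for
    ``dist_town``). ``budget_cells`` cells are converted exactly.
    """

    from_code: int
    to_code: int
    driver: str | None
    effect: float
    budget_cells: int


@dataclass
class SynthSpec:
    shape: tuple[int, int] = (200, 200)
    cell_size: float = 30.0
    class_budget: dict[int, float] = field(default_factory=lambda: dict(CMA_SHARES))
    patch_scale: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_PATCH_SCALE))
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_budget.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class budget shares must sum to 1 (got {total})")


def generate_landscape(spec: SynthSpec) -> tuple[LandUseGrid, DriverStack]:
    """Build one epoch by seeded region growing plus driver surfaces.

    Every cell is assigned, so realized class shares differ from the budget
    only by seeding/rounding effects (within 2% of target in practice).
    Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    nrow, ncol = spec.shape
    n_cells = nrow * ncol
    codes = sorted(spec.class_budget)
    budget = _cell_budgets(spec.class_budget, n_cells)
    values = _region_grow(spec, budget, rng)
    grid = LandUseGrid(
        values=values,
        cell_size=spec.cell_size,
        class_table={c: dict(DEFAULT_CLASS_TABLE.get(c, {"name": f"class{c}", "vulnerability_level": 3})) for c in codes},
        epoch_label="synthetic-epoch1",
    )
    drivers = _make_drivers(grid, rng)
    return grid, drivers


def _cell_budgets(shares: dict[int, float], n_cells: int) -> dict[int, int]:
    budget = {c: int(round(s * n_cells)) for c, s in shares.items()}
    drift = n_cells - sum(budget.values())
    budget[max(budget, key=budget.get)] += drift
    if min(budget.values()) < 1:
        raise ValueError("infeasible budget: a class has fewer than one cell")
    return budget


def _region_grow(spec: SynthSpec, budget: dict[int, int], rng: np.random.Generator) -> np.ndarray:
    nrow, ncol = spec.shape
    assigned = np.zeros((nrow, ncol), dtype=np.int64)  # 0 = unassigned
    remaining = dict(budget)
    # seeds: budget / patch_scale per class, at least 1
    order = sorted(budget, key=lambda c: -budget[c])
    for c in order:
        n_seeds = max(1, int(round(budget[c] / spec.patch_scale.get(c, 50))))
        n_seeds = min(n_seeds, remaining[c])
        free = np.flatnonzero(assigned.ravel() == 0)
        picks = rng.choice(free, size=min(n_seeds, len(free)), replace=False)
        assigned.ravel()[picks] = c
        remaining[c] -= len(picks)
    structure = ndimage.generate_binary_structure(2, 1)
    stalled: set[int] = set()
    while any(v > 0 for v in remaining.values()) and (assigned == 0).any():
        classes_left = [c for c in budget if remaining[c] > 0]
        rng.shuffle(classes_left)
        progressed = False
        for c in classes_left:
            member = assigned == c
            frontier = ndimage.binary_dilation(member, structure=structure) & (assigned == 0)
            idx = np.flatnonzero(frontier.ravel())
            if len(idx) == 0:
                # enclosed class: reseed on a random free cell (new patch)
                free = np.flatnonzero(assigned.ravel() == 0)
                if len(free) == 0:
                    break
                idx = rng.choice(free, size=1)
            take = min(remaining[c], len(idx))
            # grow a random subset of the frontier to keep boundaries irregular
            picks = rng.choice(idx, size=take, replace=False) if take < len(idx) else idx
            assigned.ravel()[picks] = c
            remaining[c] -= len(picks)
            progressed = progressed or len(picks) > 0
        if not progressed:
            break
    # safety: dump any leftovers into the nearest assigned class
    if (assigned == 0).any():
        nearest = ndimage.distance_transform_edt(assigned == 0, return_distances=False, return_indices=True)
        assigned = assigned[tuple(nearest)]
    return assigned


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _make_drivers(grid: LandUseGrid, rng: np.random.Generator) -> DriverStack:
    shape = grid.shape
    elevation = 500.0 + 300.0 * _smooth_field(shape, sigma=12, rng=rng)
    gy, gx = np.gradient(elevation, grid.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    # roads: a few random straight transects
    road = np.zeros(shape, dtype=bool)
    for _ in range(3):
        if rng.random() < 0.5:
            road[rng.integers(0, shape[0]), :] = True
        else:
            road[:, rng.integers(0, shape[1])] = True
    dist_road = ndimage.distance_transform_edt(~road) * grid.cell_size
    water = (grid.values == 5) & ~grid.nodata_mask
    if not water.any():
        water = np.zeros(shape, dtype=bool)
        water[shape[0] // 2, :] = True
    dist_river = ndimage.distance_transform_edt(~water) * grid.cell_size
    towns = (grid.values == 6) & ~grid.nodata_mask
    if not towns.any():
        towns = np.zeros(shape, dtype=bool)
        towns[rng.integers(0, shape[0]), rng.integers(0, shape[1])] = True
    dist_town = ndimage.distance_transform_edt(~towns) * grid.cell_size
    scale = max(shape) * grid.cell_size / 5.0
    population = 200.0 * np.exp(-dist_town / scale) * (1.0 + 0.2 * _smooth_field(shape, 8, rng))
    gdp = 80.0 * np.exp(-dist_town / scale) * (1.0 + 0.3 * _smooth_field(shape, 8, rng))
    layers = {
        "elevation": elevation,
        "slope": slope,
        "dist_road": dist_road,
        "dist_river": dist_river,
        "dist_town": dist_town,
        "population": population,
        "gdp": gdp,
    }
    return DriverStack(layers=layers, cell_size=grid.cell_size, nodata_mask=grid.nodata_mask.copy())


def generate_change(
    epoch1: LandUseGrid,
    drivers: DriverStack,
    rules: list[ChangeRule],
    seed: int = 0,
    epoch_label: str = "synthetic-epoch2",
) -> tuple[LandUseGrid, np.ndarray, pd.DataFrame]:
    """Apply conversion rules to produce a second epoch plus ground truth.

    Each rule converts exactly ``budget_cells`` cells of its source class,
    drawn without replacement with probability proportional to a logistic
    function of the z-scored driver (uniform when ``driver`` is None).
    Returns (epoch2 grid, boolean change mask, per-cell truth table).
    """
    rng = np.random.default_rng(seed)
    values = epoch1.values.copy()
    changed = np.zeros(epoch1.shape, dtype=bool)
    records = []
    for rule in rules:
        eligible = (values == rule.from_code) & ~epoch1.nodata_mask & ~changed
        idx = np.flatnonzero(eligible.ravel())
        if rule.budget_cells == 0:
            continue
        if len(idx) == 0:
            raise ValueError(f"rule {rule.from_code}->{rule.to_code}: empty eligible set")
        if rule.budget_cells > len(idx):
            raise ValueError(f"rule {rule.from_code}->{rule.to_code}: budget exceeds eligible cells")
        if rule.driver is None:
            logit = np.zeros(len(idx))
        else:
            z = drivers.layers[rule.driver].ravel()[idx]
            z = (z - z.mean()) / (z.std() + 1e-12)
            logit = rule.effect * z
        # Gumbel top-k = weighted sampling without replacement
        keys = logit + rng.gumbel(size=len(idx))
        picks = idx[np.argsort(-keys)[: rule.budget_cells]]
        values.ravel()[picks] = rule.to_code
        changed.ravel()[picks] = True
        for p in picks:
            records.append({"cell": int(p), "from": rule.from_code, "to": rule.to_code, "driver": rule.driver})
    epoch2 = epoch1.copy_with(values, epoch_label=epoch_label)
    truth = pd.DataFrame(records, columns=["cell", "from", "to", "driver"])
    return epoch2, changed, truth


def random_allocation(grid: LandUseGrid, demand_ha: dict[int, float], seed: int = 0) -> LandUseGrid:
    """Null allocator: meet per-class demand by relabeling uniformly random cells.

    The spatially blind baseline that any informed simulator must beat:
    surplus cells of over-supplied classes are drawn uniformly at random and
    recoded to under-supplied classes, with no drivers, neighborhoods or
    patch mechanics.
    """
    rng = np.random.default_rng(seed)
    values = grid.values.copy()
    unmasked = ~grid.nodata_mask
    per_ha = grid.cell_area_ha
    counts = grid.class_counts()
    target = {k: int(round(v / per_ha)) for k, v in demand_ha.items()}
    drift = sum(counts.values()) - sum(target.values())
    target[max(target, key=target.get)] += drift
    donors = []
    for k, c in counts.items():
        surplus = c - target.get(k, 0)
        if surplus > 0:
            pool = np.flatnonzero(((grid.values == k) & unmasked).ravel())
            donors.append(rng.choice(pool, size=surplus, replace=False))
    donor_cells = rng.permutation(np.concatenate(donors)) if donors else np.array([], dtype=int)
    pos = 0
    for k, t in target.items():
        need = t - counts.get(k, 0)
        if need > 0:
            values.ravel()[donor_cells[pos : pos + need]] = k
            pos += need
    return grid.copy_with(values, epoch_label=f"{grid.epoch_label}+null")


def cma_mini_spec(seed: int = 0) -> SynthSpec:
    """The default small fixture: 200x200 cells at 30 m, CMA-like budgets."""
    return SynthSpec(seed=seed)


def default_change_rules(n_cells_total: int) -> list[ChangeRule]:
    """A CMA-like change program: construction grows near towns at the cost
    of forest and cultivated land, water expands near rivers."""
    b = max(1, n_cells_total // 400)
    return [
        ChangeRule(2, 6, "dist_town", -2.0, 3 * b),
        ChangeRule(1, 6, "dist_town", -2.0, b),
        ChangeRule(2, 5, "dist_river", -2.0, b),
        ChangeRule(4, 2, None, 0.0, b),
    ]
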