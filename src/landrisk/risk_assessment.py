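"""Evaluation-unit ERI, kriging interpolation and natural-breaks grading.

The study region is tiled with square evaluation units (3 km x 3 km in the
original design, configurable). The landscape ecological risk index of unit
``k`` is the area-weighted sum of per-class loss indices,

    ERI_k = sum_i (A_ki / A_k) * R_i,

a convex combination of the R_i of the classes present in the unit. Unit
values are interpolated to a continuous surface by ordinary kriging and
classified into five grades with the Jenks natural-breaks optimizer.

Two metric scopes are supported: ``per_unit`` recomputes the pattern metrics
(C, N, F) inside every unit with the global vulnerability ranks (the default
for mapping — risk then reflects local pattern), while ``landscape`` uses
one global metric table for all units (reproduces whole-landscape summary
tables).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from landrisk.grid_io import AlignmentError, LandUseGrid
from landrisk.landscape_metrics import MetricWeights, metric_table

logger = logging.getLogger(__name__)


@dataclass
class EvaluationUnit:
    """One square evaluation unit: grid-aligned window ``rows`` x ``cols``."""

    id: int
    row_slice: slice
    col_slice: slice
    centroid_rc: tuple[float, float]
    area_ha: float
    composition_ha: dict[int, float]

    @property
    def inside_fraction_of(self) -> float:  # pragma: no cover - debugging aid
        return self.area_ha


@dataclass
class RiskSurface:
    """Per-unit ERI values plus derived continuous field and grade map."""

    units: list[EvaluationUnit]
    unit_values: np.ndarray
    interpolated_field: np.ndarray | None = None
    grade_map: np.ndarray | None = None
    breakpoints: np.ndarray | None = None
    cell_size: float = 30.0
    nodata_mask: np.ndarray | None = None
    epoch_label: str = ""

    def unit_frame(self) -> pd.DataFrame:
        rows = [
            {"unit": u.id, "row": u.centroid_rc[0], "col": u.centroid_rc[1], "area_ha": u.area_ha, "eri": v}
            for u, v in zip(self.units, self.unit_values)
        ]
        return pd.DataFrame(rows).set_index("unit")


def make_units(
    grid: LandUseGrid,
    side_km: float = 3.0,
    min_inside_fraction: float = 0.5,
) -> list[EvaluationUnit]:
    """Tile the grid's bounding box with square units of side ``side_km``.

    Unit bounds are snapped to whole cells (``side_km`` is rounded to the
    nearest cell multiple, at least one cell). Units whose unmasked fraction
    is below ``min_inside_fraction`` are dropped; partially-inside edge units
    above the threshold are retained with their true inside area.
    """
    if side_km <= 0:
        raise ValueError("side_km must be > 0")
    side_cells = max(1, round(side_km * 1000.0 / grid.cell_size))
    nrow, ncol = grid.shape
    units: list[EvaluationUnit] = []
    uid = 0
    for r0 in range(0, nrow, side_cells):
        for c0 in range(0, ncol, side_cells):
            rs = slice(r0, min(r0 + side_cells, nrow))
            cs = slice(c0, min(c0 + side_cells, ncol))
            block_mask = grid.nodata_mask[rs, cs]
            n_inside = int((~block_mask).sum())
            n_total = block_mask.size
            if n_total == 0 or n_inside / n_total < max(min_inside_fraction, 1e-12):
                continue
            vals = grid.values[rs, cs][~block_mask]
            comp = {code: float((vals == code).sum()) * grid.cell_area_ha for code in grid.class_codes()}
            units.append(
                EvaluationUnit(
                    id=uid,
                    row_slice=rs,
                    col_slice=cs,
                    centroid_rc=((rs.start + rs.stop - 1) / 2.0, (cs.start + cs.stop - 1) / 2.0),
                    area_ha=n_inside * grid.cell_area_ha,
                    composition_ha=comp,
                )
            )
            uid += 1
    logger.info("retained %d evaluation units (side %d cells)", len(units), side_cells)
    return units


def unit_eri(unit: EvaluationUnit, loss_by_class: dict[int, float]) -> float:
    """ERI_k = sum_i (A_ki / A_k) * R_i over classes present in the unit."""
    if unit.area_ha <= 0:
        raise ValueError("unit has zero inside area")
    total = 0.0
    for code, a_ki in unit.composition_ha.items():
        if a_ki <= 0:
            continue
        r_i = loss_by_class.get(code)
        if r_i is None or np.isnan(r_i):
            raise ValueError(f"loss index missing for class {code} present in unit {unit.id}")
        total += (a_ki / unit.area_ha) * r_i
    return total


def landscape_eri(grid: LandUseGrid, weights: MetricWeights | None = None) -> float:
    """Whole-landscape ERI: one degenerate unit covering the full region."""
    table = metric_table(grid, weights)
    loss = table["R"].to_dict()
    comp = grid.class_areas_ha()
    a = grid.landscape_area_ha
    return sum((a_i / a) * loss[c] for c, a_i in comp.items() if a_i > 0)


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

def _spherical(h: np.ndarray, nugget: float, sill: float, rng: float) -> np.ndarray:
    g = np.where(
        h >= rng,
        nugget + sill,
        nugget + sill * (1.5 * h / rng - 0.5 * (h / rng) ** 3),
    )
    return np.where(h == 0, 0.0, g)


def fit_variogram(points: np.ndarray, values: np.ndarray, nugget: float = 0.0) -> tuple[float, float, float]:
    """Method-of-moments spherical variogram fit.

    Empirical semivariances are binned over pairwise distances; sill and
    range are fit by least squares over a coarse range grid. Returns
    ``(nugget, sill, range)``. Degenerate (constant) data fall back to a
    unit sill over the maximum distance, which leaves ordinary-kriging
    weights well-defined.
    """
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    gamma = 0.5 * (values[:, None] - values[None, :]) ** 2
    iu = np.triu_indices(len(values), k=1)
    dist, gam = d[iu], gamma[iu]
    dmax = dist.max()
    if dmax == 0 or gam.max() == 0:
        return nugget, 1.0, max(dmax, 1.0)
    nbin = 12
    edges = np.linspace(0, dmax * 0.75, nbin + 1)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist > lo) & (dist <= hi)
        if sel.sum() >= 3:
            centers.append(dist[sel].mean())
            means.append(gam[sel].mean())
    centers = np.array(centers)
    means = np.array(means)
    if len(centers) < 2:
        return nugget, float(gam.mean()), float(dmax / 2)
    best = None
    for rng in np.linspace(dmax * 0.1, dmax, 25):
        base = _spherical(centers, 0.0, 1.0, rng) - nugget
        denom = float((base**2).sum())
        if denom == 0:
            continue
        sill = max(float((base * (means - nugget)).sum()) / denom, 1e-12)
        sse = float(((nugget + sill * base - means) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, sill, rng)
    _, sill, rng = best
    return nugget, sill, float(rng)


def krige_surface(
    points: np.ndarray,
    values: np.ndarray,
    shape: tuple[int, int],
    nugget: float = 0.0,
    variogram: tuple[float, float, float] | None = None,
    block: int = 4096,
) -> np.ndarray:
    """Ordinary kriging of unit values onto a raster grid.

    Parameters
    ----------
    points : (n, 2) sample coordinates in (row, col) cell units.
    values : (n,) sample values (e.g. per-unit ERI).
    shape : target raster shape.
    nugget : variogram nugget; with 0 the interpolator is exact at the
        sample points (reproduces each unit's value there).
    variogram : optional fixed (nugget, sill, range); fitted if omitted.

    Raises on duplicate sample points (singular kriging system).
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise ValueError("kriging needs at least 2 sample points")
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    if np.any(d[np.triu_indices(len(points), k=1)] == 0):
        raise ValueError("duplicate sample centroids: singular kriging system")
    if variogram is None:
        variogram = fit_variogram(points, values, nugget=nugget)
    nug, sill, rng = variogram
    n = len(points)
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = _spherical(d, nug, sill, rng)
    K[n, :] = 1.0
    K[:, n] = 1.0
    K[n, n] = 0.0
    rows, cols = np.indices(shape)
    targets = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    out = np.empty(len(targets))
    from scipy.linalg import lu_factor, lu_solve

    lu = lu_factor(K)
    for start in range(0, len(targets), block):
        t = targets[start : start + block]
        dh = np.sqrt(((t[:, None, :] - points[None, :, :]) ** 2).sum(-1))
        rhs = np.empty((len(t), n + 1))
        rhs[:, :n] = _spherical(dh, nug, sill, rng)
        rhs[:, n] = 1.0
        w = lu_solve(lu, rhs.T).T
        out[start : start + block] = w[:, :n] @ values
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# Jenks natural breaks
# ---------------------------------------------------------------------------

def jenks_breaks(values: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Jenks natural-breaks classification: the 1-D partition of the sorted
    values into ``n_classes`` contiguous groups minimizing total within-class
    sum of squared deviations.

    Returns the ``n_classes - 1`` interior breakpoints (upper bound of each
    class but the last, as data values). Exact O(k n²) dynamic program.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(x)
    if len(np.unique(x)) < n_classes:
        raise ValueError("fewer distinct values than classes")
    # prefix sums give O(1) within-class SSE; DP inner minimization vectorized
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x**2)])
    cost = np.full((n_classes + 1, n + 1), np.inf)
    back = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, n_classes + 1):
        for j in range(k, n + 1):
            i = np.arange(k - 1, j)
            m = j - i
            s = cs[j] - cs[i]
            sse = (cs2[j] - cs2[i]) - s * s / m
            total = cost[k - 1, k - 1 : j] + sse
            arg = int(np.argmin(total))
            cost[k, j] = total[arg]
            back[k, j] = arg + k - 1
    cuts = []
    j = n
    for k in range(n_classes, 0, -1):
        i = back[k, j]
        cuts.append(i)
        j = i
    cuts = sorted(cuts)[1:]  # drop leading 0
    return np.array([x[c - 1] for c in cuts])


def classify_risk(
    values: np.ndarray,
    n_classes: int = 5,
    breakpoints: np.ndarray | None = None,
    max_jenks_n: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Grade values 1..n_classes by natural breaks (or given breakpoints).

    For inputs larger than ``max_jenks_n`` the breaks are computed on an
    evenly spaced quantile sample of the sorted values (the exact DP is
    quadratic). Returns ``(breakpoints, grades)``; grade g means
    ``break[g-2] < value <= break[g-1]`` with open ends.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if breakpoints is None:
        data = np.sort(arr[finite].ravel())
        if len(data) > max_jenks_n:
            data = data[np.linspace(0, len(data) - 1, max_jenks_n).astype(int)]
        breakpoints = jenks_breaks(data, n_classes)
    breakpoints = np.asarray(breakpoints, dtype=float)
    grades = np.zeros(arr.shape, dtype=np.int8)
    grades[finite] = 1 + np.searchsorted(breakpoints, arr[finite], side="left")
    return breakpoints, grades


def grade_area_table(grade_maps: dict[str, np.ndarray], cell_area_km2: float, n_classes: int = 5) -> pd.DataFrame:
    """Km² per grade per epoch plus consecutive-epoch deltas (sum to 0)."""
    epochs = list(grade_maps)
    shapes = {m.shape for m in grade_maps.values()}
    if len(shapes) != 1:
        raise AlignmentError("grade maps are not aligned")
    rows = {}
    for ep, gm in grade_maps.items():
        rows[ep] = [float((gm == g).sum()) * cell_area_km2 for g in range(1, n_classes + 1)]
    df = pd.DataFrame(rows, index=[f"grade_{g}" for g in range(1, n_classes + 1)]).T
    for a, b in itertools.pairwise(epochs):
        df.loc[f"{a}->{b}"] = df.loc[b] - df.loc[a]
    return df


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def assess_risk(
    grid: LandUseGrid,
    weights: MetricWeights | None = None,
    side_km: float = 3.0,
    min_inside_fraction: float = 0.5,
    metric_scope: str = "per_unit",
    n_classes: int = 5,
    breakpoints: np.ndarray | None = None,
    krige: bool = True,
) -> RiskSurface:
    """Full risk assessment of one epoch: units -> ERI -> kriging -> grades.

    ``metric_scope`` is ``"per_unit"`` (pattern metrics recomputed inside
    each unit, global vulnerability) or ``"landscape"`` (one global metric
    table feeds every unit).
    """
    if weights is None:
        weights = MetricWeights()
    if metric_scope not in ("per_unit", "landscape"):
        raise ValueError("metric_scope must be 'per_unit' or 'landscape'")
    units = make_units(grid, side_km=side_km, min_inside_fraction=min_inside_fraction)
    if not units:
        raise ValueError("no evaluation units retained")
    if metric_scope == "landscape":
        loss = metric_table(grid, weights)["R"].to_dict()
        eri = np.array([unit_eri(u, loss) for u in units])
    else:
        eri = np.empty(len(units))
        for i, u in enumerate(units):
            scope = np.zeros(grid.shape, dtype=bool)
            scope[u.row_slice, u.col_slice] = True
            tab = metric_table(grid, weights, scope=scope)
            loss = tab["R"].to_dict()
            eri[i] = unit_eri(u, loss)
    surface = RiskSurface(
        units=units,
        unit_values=eri,
        cell_size=grid.cell_size,
        nodata_mask=grid.nodata_mask.copy(),
        epoch_label=grid.epoch_label,
    )
    if krige and len(units) >= 10:
        pts = np.array([u.centroid_rc for u in units])
        surface.interpolated_field = krige_surface(pts, eri, grid.shape)
    else:
        # nearest-unit fill keeps the pipeline usable on tiny toy grids
        field = np.zeros(grid.shape)
        for u, v in zip(units, eri):
            field[u.row_slice, u.col_slice] = v
        surface.interpolated_field = field
    surface.interpolated_field[grid.nodata_mask] = np.nan
    finite = surface.interpolated_field[~grid.nodata_mask]
    if breakpoints is None and len(np.unique(finite)) < n_classes:
        # degenerate surface (e.g. a single unit): everything is grade 1
        bp = np.array([])
        grades = np.where(grid.nodata_mask, 0, 1).astype(np.int8)
    else:
        bp, grades = classify_risk(surface.interpolated_field, n_classes=n_classes, breakpoints=breakpoints)
        grades[grid.nodata_mask] = 0
    surface.breakpoints = bp
    surface.grade_map = grades
    return surface
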