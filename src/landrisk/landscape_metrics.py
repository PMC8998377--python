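"""Per-class landscape-pattern indices and the disturbance / loss indices.

For each land-use class *i* with ``n_i`` patches, class area ``A_i``
(hectares), class perimeter ``P_i`` (meters) and landscape area ``A``
(hectares):

* fragmentation        C_i = n_i / A_i
* separation           N_i = (1/2) * sqrt(n_i / A) * (A / A_i)
* fractal dimension    F_i = 2 * ln(P_i / 4) / ln(A_i')   (A_i' in m²)
* vulnerability        V_i = normalized expert rank (1–5, low to high)
* disturbance          E_i = a*C_i + b*N_i + c*F_i,   a + b + c = 1
* loss index           R_i = E_i * V_i

The default disturbance weights are (a, b, c) = (0.5, 0.3, 0.2). Metrics of
an empty class are *absent* (NaN), never zero: a zero disturbance would
silently lower the risk index downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from landrisk.grid_io import LandUseGrid, PatchSet, extract_patches

logger = logging.getLogger(__name__)

#: Default vulnerability ranks for the six-class scheme (low to high):
#: 5 water, 4 cultivated and orchard, 3 grassland, 2 forest, 1 construction.
DEFAULT_VULNERABILITY_LEVELS = {1: 4, 2: 2, 3: 4, 4: 3, 5: 5, 6: 1}


@dataclass
class MetricWeights:
    """Weights of the disturbance index and vulnerability ranks.

    ``a``, ``b``, ``c`` weight fragmentation, separation and fractal
    dimension; they must be non-negative and sum to 1. ``vulnerability_levels``
    maps class code to an integer rank 1–5 (higher = more vulnerable);
    ``vulnerability_mode`` selects sum-normalization (``"sum"``, V_i =
    level_i / Σ levels, the default) or max-normalization (``"max"``,
    V_i = level_i / max level).
    """

    a: float = 0.5
    b: float = 0.3
    c: float = 0.2
    vulnerability_levels: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_VULNERABILITY_LEVELS))
    vulnerability_mode: str = "sum"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.a + self.b + self.c - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        for code, lvl in self.vulnerability_levels.items():
            if not 1 <= lvl <= 5:
                raise ValueError(f"vulnerability level for class {code} outside 1-5")
        if self.vulnerability_mode not in ("sum", "max"):
            raise ValueError("vulnerability_mode must be 'sum' or 'max'")


def fragmentation(n_i: float, area_ha: float) -> float:
    """C_i = n_i / A_i (patches per hectare). NaN for an empty class."""
    if area_ha <= 0:
        return math.nan
    return n_i / area_ha


def separation(n_i: float, area_ha: float, landscape_area_ha: float) -> float:
    """N_i = (1/2) * sqrt(n_i / A) * (A / A_i). NaN for an empty class."""
    if area_ha <= 0:
        return math.nan
    if landscape_area_ha < area_ha:
        raise ValueError("landscape area smaller than class area")
    return 0.5 * math.sqrt(n_i / landscape_area_ha) * (landscape_area_ha / area_ha)


def fractal_dimension(perimeter_m: float, area_m2: float, clip: bool = True) -> float:
    """F_i = 2 * ln(P_i / 4) / ln(A_i) with P_i in meters and A_i in m².

    A square patch of side s has P = 4s, A = s², hence F = 1; space-filling
    shapes approach 2. Values outside [1, 2] (possible for thin or tiny
    patches) are clipped with a warning when ``clip`` is set.
    """
    if perimeter_m <= 4 or area_m2 <= 1:
        return math.nan
    f = 2.0 * math.log(perimeter_m / 4.0) / math.log(area_m2)
    if clip and not 1.0 <= f <= 2.0:
        logger.warning("fractal dimension %.4f outside [1, 2]; clipped", f)
        f = min(2.0, max(1.0, f))
    return f


def vulnerability(levels: dict[int, int], mode: str = "sum") -> dict[int, float]:
    """Normalize expert vulnerability ranks to V_i.

    ``sum`` mode: V_i = level_i / Σ_j level_j (Σ V_i = 1).
    ``max`` mode: V_i = level_i / max_j level_j (max V_i = 1).
    """
    if not levels:
        raise ValueError("no vulnerability levels given")
    if mode == "sum":
        denom = sum(levels.values())
    elif mode == "max":
        denom = max(levels.values())
    else:
        raise ValueError("mode must be 'sum' or 'max'")
    return {code: lvl / denom for code, lvl in levels.items()}


def disturbance(c_i: float, n_i: float, f_i: float, weights: MetricWeights) -> float:
    """E_i = a*C_i + b*N_i + c*F_i."""
    return weights.a * c_i + weights.b * n_i + weights.c * f_i


def loss_index(e_i: float, v_i: float) -> float:
    """R_i = E_i * V_i, the per-class ecological-loss contribution."""
    return e_i * v_i


def metric_table(
    grid: LandUseGrid,
    weights: MetricWeights | None = None,
    scope: np.ndarray | None = None,
    connectivity: int = 8,
    patches: PatchSet | None = None,
) -> pd.DataFrame:
    """Full per-class metric table for a grid or a sub-region of it.

    Parameters
    ----------
    grid : land-use raster.
    weights : disturbance weights and vulnerability scheme (defaults apply).
    scope : optional boolean mask restricting the computation to a region
        (e.g. one evaluation unit); patches are then delineated inside the
        scope only.
    patches : precomputed :class:`PatchSet` for the full grid (ignored when
        ``scope`` is given).

    Returns
    -------
    DataFrame indexed by class code with columns ``name, n, A_ha, P_m, C, N,
    F, V, E, R``. Classes absent from the scope carry NaN metrics and are
    meant to contribute zero downstream.
    """
    if weights is None:
        weights = MetricWeights()
    if scope is not None:
        scoped_mask = grid.nodata_mask | ~np.asarray(scope, dtype=bool)
        if scoped_mask.all():
            raise ValueError("empty scope")
        grid = LandUseGrid(
            values=grid.values,
            cell_size=grid.cell_size,
            nodata_mask=scoped_mask,
            class_table=dict(grid.class_table),
            epoch_label=grid.epoch_label,
        )
        patches = None
    if patches is None:
        patches = extract_patches(grid, connectivity=connectivity)
    v = vulnerability(weights.vulnerability_levels, mode=weights.vulnerability_mode)
    A = patches.landscape_area_ha
    rows = []
    for code in grid.class_codes():
        n_i = patches.n[code]
        a_ha = patches.area_ha[code]
        p_m = patches.perimeter_m[code]
        c_i = fragmentation(n_i, a_ha)
        sep = separation(n_i, a_ha, A)
        f_i = fractal_dimension(p_m, a_ha * 1e4)
        e_i = disturbance(c_i, sep, f_i, weights) if a_ha > 0 else math.nan
        r_i = loss_index(e_i, v[code]) if a_ha > 0 else math.nan
        rows.append(
            {
                "class": code,
                "name": grid.class_table[code]["name"],
                "n": n_i,
                "A_ha": a_ha,
                "P_m": p_m,
                "C": c_i,
                "N": sep,
                "F": f_i,
                "V": v[code],
                "E": e_i,
                "R": r_i,
            }
        )
    df = pd.DataFrame(rows).set_index("class")
    df.attrs["landscape_area_ha"] = A
    df.attrs["epoch"] = grid.epoch_label
    return df
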