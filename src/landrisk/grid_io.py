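"""Raster I/O, class schemes, masks and per-class patch extraction.

A land-use map is a categorical raster: one integer class code per cell on a
regular square grid. Patches (connected components of one class) are the
atoms of every landscape-pattern metric downstream, so this module owns both
the container types and patch delineation.

Supported on-disk formats are single-band TIFF (via :mod:`tifffile`) and the
plain-text ESRI ASCII grid. Cell size for TIFF rasters travels in a small
YAML sidecar (``<raster>.meta.yaml``) since plain TIFF carries no georeference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Default six-class scheme for the Hainan CMA-style landscapes:
#: code -> (name, vulnerability level 1-5, low to high).
DEFAULT_CLASS_TABLE: dict[int, dict] = {
    1: {"name": "cultivated", "vulnerability_level": 4},
    2: {"name": "forest", "vulnerability_level": 2},
    3: {"name": "orchard", "vulnerability_level": 4},
    4: {"name": "grassland", "vulnerability_level": 3},
    5: {"name": "water", "vulnerability_level": 5},
    6: {"name": "construction", "vulnerability_level": 1},
}


class AlignmentError(ValueError):
    """Two grids do not share shape, cell size and mask."""


@dataclass
class LandUseGrid:
    """Categorical land-use raster.

    Parameters
    ----------
    values : (nrow, ncol) integer array of class codes. Row-major, origin
        top-left, values refer to cell centers.
    cell_size : cell edge length in meters (> 0).
    nodata_mask : boolean array, True where the cell is outside the study
        region (masked). Masked cells are excluded from every computation.
    class_table : mapping code -> {"name": str, "vulnerability_level": int}.
    epoch_label : free-text label of the epoch (e.g. "2000").
    """

    values: np.ndarray
    cell_size: float
    nodata_mask: np.ndarray | None = None
    class_table: Mapping[int, dict] = field(default_factory=lambda: dict(DEFAULT_CLASS_TABLE))
    epoch_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.mod(self.values[np.isfinite(self.values)], 1) == 0):
                raise ValueError("land-use values must be integer class codes")
            self.values = self.values.astype(np.int64)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")
        unknown = self._unknown_codes()
        if unknown.any():
            n = int(unknown.sum())
            logger.warning("masking %d cell(s) with codes not in class_table", n)
            self.nodata_mask = self.nodata_mask | unknown
        if self.nodata_mask.all():
            raise ValueError("grid is fully masked")

    def _unknown_codes(self) -> np.ndarray:
        known = np.array(sorted(self.class_table), dtype=self.values.dtype)
        return ~np.isin(self.values, known) & ~self.nodata_mask

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares."""
        return self.cell_size**2 / 1e4

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    @property
    def n_unmasked(self) -> int:
        return int((~self.nodata_mask).sum())

    @property
    def landscape_area_ha(self) -> float:
        """Total unmasked area A in hectares."""
        return self.n_unmasked * self.cell_area_ha

    def class_codes(self) -> list[int]:
        return sorted(self.class_table)

    def class_areas_ha(self) -> dict[int, float]:
        """Per-class area in hectares (0.0 for absent classes)."""
        out = {}
        vals = self.values[~self.nodata_mask]
        for code in self.class_codes():
            out[code] = float((vals == code).sum()) * self.cell_area_ha
        return out

    def class_areas_km2(self) -> dict[int, float]:
        return {c: a / 100.0 for c, a in self.class_areas_ha().items()}

    def class_counts(self) -> dict[int, int]:
        vals = self.values[~self.nodata_mask]
        return {code: int((vals == code).sum()) for code in self.class_codes()}

    def aligned_with(self, other: "LandUseGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and bool(np.array_equal(self.nodata_mask, other.nodata_mask))
        )

    def require_aligned(self, other: "LandUseGrid") -> None:
        if not self.aligned_with(other):
            raise AlignmentError("grids are not aligned (shape/cell_size/mask differ)")

    def copy_with(self, values: np.ndarray, epoch_label: str | None = None) -> "LandUseGrid":
        return LandUseGrid(
            values=np.asarray(values).copy(),
            cell_size=self.cell_size,
            nodata_mask=self.nodata_mask.copy(),
            class_table=dict(self.class_table),
            epoch_label=self.epoch_label if epoch_label is None else epoch_label,
        )


@dataclass
class DriverStack:
    """Named continuous covariate rasters aligned to a land-use grid.

    Typical layers: elevation, slope, distance to roads, distance to rivers,
    distance to town centers, population density, GDP density.
    """

    layers: dict[str, np.ndarray]
    cell_size: float
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.nodata_mask.shape:
                raise AlignmentError(f"driver layer {name!r} shape mismatch")
            if not np.isfinite(arr[~self.nodata_mask]).all():
                raise ValueError(f"driver layer {name!r} has non-finite unmasked values")
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def as_matrix(self, cells: np.ndarray | None = None) -> np.ndarray:
        """Feature matrix (n_cells, n_drivers); rows follow ``cells`` (flat indices)
        or all unmasked cells in row-major order."""
        flat = [self.layers[n].ravel() for n in self.names]
        X = np.column_stack(flat)
        if cells is None:
            cells = np.flatnonzero(~self.nodata_mask.ravel())
        return X[cells]

    def aligned_with(self, grid: LandUseGrid) -> bool:
        return self.nodata_mask.shape == grid.shape and self.cell_size == grid.cell_size


@dataclass
class PatchSet:
    """Per-class connected components of a categorical raster.

    ``n`` patch counts, ``area_ha`` class areas (ha), ``perimeter_m`` class
    perimeters (meters; includes edges against the mask and the raster
    boundary, the common landscape-metrics convention), and a label matrix
    assigning every unmasked cell a globally unique patch id (0 = masked).
    """

    n: dict[int, int]
    area_ha: dict[int, float]
    perimeter_m: dict[int, float]
    patch_labels: np.ndarray
    connectivity: int
    landscape_area_ha: float


def extract_patches(grid: LandUseGrid, connectivity: int = 8) -> PatchSet:
    """Delineate per-class patches and tally counts, areas and perimeters.

    Parameters
    ----------
    grid : the categorical raster.
    connectivity : 4 (rook, edge-sharing) or 8 (queen, corner-sharing;
        default, the common landscape-metrics convention).

    Notes
    -----
    Perimeter counts every cell edge between a class cell and anything that
    is not that class — another class, a masked cell, or the raster boundary —
    times the cell size. Empty classes get ``n = area = perimeter = 0``.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels = np.zeros(grid.shape, dtype=np.int32)
    n: dict[int, int] = {}
    area: dict[int, float] = {}
    perim: dict[int, float] = {}
    next_id = 0
    unmasked = ~grid.nodata_mask
    for code in grid.class_codes():
        member = (grid.values == code) & unmasked
        lab, k = ndimage.label(member, structure=structure)
        labels[member] = lab[member] + next_id
        next_id += k
        n[code] = int(k)
        area[code] = float(member.sum()) * grid.cell_area_ha
        perim[code] = _class_perimeter(member) * grid.cell_size
    return PatchSet(
        n=n,
        area_ha=area,
        perimeter_m=perim,
        patch_labels=labels,
        connectivity=connectivity,
        landscape_area_ha=grid.landscape_area_ha,
    )


def _class_perimeter(member: np.ndarray) -> float:
    """Number of exposed cell edges of a boolean class mask (boundary counts)."""
    padded = np.pad(member, 1, constant_values=False)
    edges = 0
    for ax in (0, 1):
        diff = padded.astype(np.int8) - np.roll(padded, 1, axis=ax).astype(np.int8)
        edges += int(np.abs(diff).sum())
    return float(edges)


def crosstab_change(grid_a: LandUseGrid, grid_b: LandUseGrid) -> pd.DataFrame:
    """Area transition matrix (km²) from ``grid_a`` classes to ``grid_b`` classes.

    Row/column sums equal each epoch's class areas. The conventional
    two-digit transition code for a cell moving from class ``i`` to class
    ``j`` is ``10*i + j`` (e.g. 23 = forest to orchard under the default
    scheme); :func:`transition_codes` renders that view.
    """
    grid_a.require_aligned(grid_b)
    codes = np.array(sorted(set(grid_a.class_codes()) | set(grid_b.class_codes())))
    unmasked = ~grid_a.nodata_mask
    ai = np.searchsorted(codes, grid_a.values[unmasked])
    bi = np.searchsorted(codes, grid_b.values[unmasked])
    mat = np.zeros((len(codes), len(codes)))
    np.add.at(mat, (ai, bi), grid_a.cell_area_km2)
    return pd.DataFrame(mat, index=codes, columns=codes)


def transition_codes(change: pd.DataFrame) -> pd.DataFrame:
    """Long-form change table with concatenated-digit transition codes."""
    rows = []
    for i in change.index:
        for j in change.columns:
            area = change.loc[i, j]
            if i != j and area > 0:
                rows.append({"code": int(f"{i}{j}"), "from": i, "to": j, "area_km2": area})
    return pd.DataFrame(rows, columns=["code", "from", "to", "area_km2"])


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_ASC_NODATA = -9999


def read_landuse(
    path: str | Path,
    class_table: Mapping[int, dict] | None = None,
    cell_size: float | None = None,
    epoch_label: str = "",
) -> LandUseGrid:
    """Read a categorical raster from TIFF or ESRI ASCII grid.

    Cells whose code is absent from ``class_table`` are masked with a logged
    warning count. For TIFF, cell size comes from ``cell_size`` or the
    ``<path>.meta.yaml`` sidecar (key ``cell_size``); ASCII grids carry it in
    their header.
    """
    path = Path(path)
    if class_table is None:
        class_table = dict(DEFAULT_CLASS_TABLE)
    if path.suffix.lower() in (".asc", ".txt"):
        values, mask, cs = _read_ascii_grid(path)
        if cell_size is not None:
            cs = cell_size
    else:
        values, mask, cs = _read_tiff(path, cell_size)
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.mod(values[~mask], 1) == 0):
            raise ValueError(f"{path}: band is not integer-coded")
        values = values.astype(np.int64)
    return LandUseGrid(
        values=values,
        cell_size=cs,
        nodata_mask=mask,
        class_table=dict(class_table),
        epoch_label=epoch_label or path.stem,
    )


def write_landuse(grid: LandUseGrid, path: str | Path) -> Path:
    """Write a grid as ESRI ASCII (.asc) or single-band TIFF + sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".asc", ".txt"):
        _write_ascii_grid(path, grid.values, grid.nodata_mask, grid.cell_size)
    else:
        _write_tiff(path, grid.values, grid.nodata_mask, grid.cell_size, nodata=_ASC_NODATA)
    return path


def read_driver(path: str | Path, cell_size: float | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a continuous driver raster; returns (values, nodata_mask, cell_size)."""
    path = Path(path)
    if path.suffix.lower() in (".asc", ".txt"):
        values, mask, cs = _read_ascii_grid(path, dtype=float)
    else:
        values, mask, cs = _read_tiff(path, cell_size)
        values = values.astype(float)
    if cell_size is not None:
        cs = cell_size
    return values, mask, cs


def read_drivers(paths: Mapping[str, str | Path], grid: LandUseGrid) -> DriverStack:
    """Read named driver rasters and align them against ``grid``."""
    layers = {}
    for name, p in paths.items():
        values, mask, cs = read_driver(p, cell_size=grid.cell_size)
        if values.shape != grid.shape:
            raise AlignmentError(f"driver {name!r} shape {values.shape} != grid {grid.shape}")
        values = values.copy()
        values[mask] = np.nan
        # fill masked driver cells that the landscape mask keeps (nearest value)
        bad = np.isnan(values) & ~grid.nodata_mask
        if bad.any():
            idx = ndimage.distance_transform_edt(np.isnan(values), return_distances=False, return_indices=True)
            values = values[tuple(idx)]
        values[grid.nodata_mask] = 0.0
        layers[name] = values
    return DriverStack(layers=layers, cell_size=grid.cell_size, nodata_mask=grid.nodata_mask.copy())


def write_driver(values: np.ndarray, nodata_mask: np.ndarray, cell_size: float, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".asc", ".txt"):
        _write_ascii_grid(path, values, nodata_mask, cell_size, fmt="%.6g")
    else:
        _write_tiff(path, values.astype(np.float32), nodata_mask, cell_size, nodata=float(_ASC_NODATA))
    return path


def _read_ascii_grid(path: Path, dtype=None) -> tuple[np.ndarray, np.ndarray, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
                "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", _ASC_NODATA)
    mask = data == nodata
    if dtype is None and np.all(np.mod(data[~mask], 1) == 0):
        data = data.astype(np.int64)
    return data, mask, float(header["cellsize"])


def _write_ascii_grid(path: Path, values: np.ndarray, mask: np.ndarray, cell_size: float, fmt: str = "%d") -> None:
    out = np.array(values, dtype=float if fmt != "%d" else np.int64)
    out[mask] = _ASC_NODATA
    nrows, ncols = out.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\nxllcorner 0.0\nyllcorner 0.0\n")
        fh.write(f"cellsize {cell_size}\nNODATA_value {_ASC_NODATA}\n")
        np.savetxt(fh, out, fmt=fmt)


def _read_tiff(path: Path, cell_size: float | None) -> tuple[np.ndarray, np.ndarray, float]:
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {arr.shape}")
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    nodata = None
    cs = cell_size
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        cs = cs or meta.get("cell_size")
        nodata = meta.get("nodata")
    if cs is None:
        raise ValueError(f"{path}: cell size unknown; pass cell_size or provide {sidecar.name}")
    if nodata is None:
        nodata = _ASC_NODATA
    if np.issubdtype(arr.dtype, np.floating):
        mask = ~np.isfinite(arr) | (arr == nodata)
    else:
        mask = arr == nodata
    return arr, mask, float(cs)


def _write_tiff(path: Path, values: np.ndarray, mask: np.ndarray, cell_size: float, nodata) -> None:
    import tifffile

    out = values.copy()
    out[mask] = nodata
    tifffile.imwrite(path, out)
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump({"cell_size": float(cell_size), "nodata": nodata}))
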