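"""Map-agreement statistics and risk-surface comparison.

Agreement between a simulated and a reference categorical map is summarized
by the cell-wise confusion matrix, overall accuracy (OA = trace / total)
and Cohen's kappa, kappa = (OA - p_e) / (1 - p_e) with expected agreement
p_e from the marginal products. Producer's accuracy is per-class recall
(reference margin), user's accuracy per-class precision (simulated margin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from landrisk.grid_io import LandUseGrid
from landrisk.risk_assessment import RiskSurface


@dataclass
class AgreementReport:
    confusion: pd.DataFrame          # rows = reference, cols = simulated (cells)
    overall_accuracy: float
    kappa: float
    producer_accuracy: dict[int, float]
    user_accuracy: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, "producer_accuracy": self.producer_accuracy[c], "user_accuracy": self.user_accuracy[c]}
            for c in self.confusion.index
        ]
        return pd.DataFrame(rows).set_index("class")


def agreement(simulated: LandUseGrid, reference: LandUseGrid) -> AgreementReport:
    """Cell-wise confusion matrix, overall accuracy and kappa.

    Raises on misaligned grids and on degenerate marginals (p_e = 1, e.g. a
    single-class reference matched by a single-class simulation), where
    kappa is undefined.
    """
    simulated.require_aligned(reference)
    unmasked = ~simulated.nodata_mask
    sim = simulated.values[unmasked]
    ref = reference.values[unmasked]
    if sim.size == 0:
        raise ValueError("empty overlap")
    codes = sorted(set(np.unique(sim)) | set(np.unique(ref)))
    n = len(codes)
    ri = np.searchsorted(codes, ref)
    si = np.searchsorted(codes, sim)
    mat = np.zeros((n, n), dtype=np.int64)
    np.add.at(mat, (ri, si), 1)
    total = mat.sum()
    oa = float(np.trace(mat)) / total
    p_e = float((mat.sum(axis=1) * mat.sum(axis=0)).sum()) / total**2
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("kappa undefined: degenerate marginals (expected agreement = 1)")
    kappa = (oa - p_e) / (1.0 - p_e)
    ref_tot = mat.sum(axis=1)
    sim_tot = mat.sum(axis=0)
    producer = {c: (mat[i, i] / ref_tot[i] if ref_tot[i] else float("nan")) for i, c in enumerate(codes)}
    user = {c: (mat[i, i] / sim_tot[i] if sim_tot[i] else float("nan")) for i, c in enumerate(codes)}
    confusion = pd.DataFrame(mat, index=codes, columns=codes)
    return AgreementReport(
        confusion=confusion,
        overall_accuracy=oa,
        kappa=float(kappa),
        producer_accuracy=producer,
        user_accuracy=user,
    )


def risk_delta_map(surface_a: RiskSurface, surface_b: RiskSurface) -> tuple[np.ndarray, pd.DataFrame]:
    """Signed risk change field (b - a) and grade-transition crosstab.

    Antisymmetric under argument swap. The crosstab counts cells per
    (grade in a, grade in b) pair.
    """
    fa, fb = surface_a.interpolated_field, surface_b.interpolated_field
    if fa is None or fb is None or fa.shape != fb.shape:
        raise ValueError("surfaces not aligned or not interpolated")
    delta = fb - fa
    ga, gb = surface_a.grade_map, surface_b.grade_map
    grades = sorted(set(np.unique(ga)) | set(np.unique(gb)))
    gi = {g: i for i, g in enumerate(grades)}
    mat = np.zeros((len(grades), len(grades)), dtype=np.int64)
    np.add.at(mat, ([gi[g] for g in ga.ravel()], [gi[g] for g in gb.ravel()]), 1)
    table = pd.DataFrame(mat, index=grades, columns=grades)
    return delta, table
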