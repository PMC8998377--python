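"""Land-expansion analysis: learn per-class growth probabilities from change.

Between two observed epochs, the cells that *became* class k (expansion of
k) are positives and a background draw of unchanged/other cells are
negatives; a random-forest classifier per class maps driver covariates to a
development-probability surface P_{i,k} in [0, 1] together with driver
importances. Sampling is stratified: every expansion cell is eligible as a
positive, negatives are drawn uniformly from the rest, at an overall rate
(default 1% of eligible cells, floor applied so tiny maps still train).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from landrisk.grid_io import DriverStack, LandUseGrid

logger = logging.getLogger(__name__)


@dataclass
class ExpansionSample:
    """Training sample for one class's growth model."""

    class_code: int
    cells: np.ndarray        # flat indices into the raster
    labels: np.ndarray       # 1 = expanded to class, 0 = background
    sampling_rate: float
    rng_seed: int


@dataclass
class GrowthProbability:
    """Per-class development-probability surfaces and driver importances."""

    prob: dict[int, np.ndarray]               # class -> (nrow, ncol) in [0, 1]
    importances: dict[int, dict[str, float]]  # class -> driver -> importance
    oob_score: dict[int, float]

    def copy(self) -> "GrowthProbability":
        return GrowthProbability(
            prob={k: v.copy() for k, v in self.prob.items()},
            importances={k: dict(v) for k, v in self.importances.items()},
            oob_score=dict(self.oob_score),
        )


def extract_expansion(epoch1: LandUseGrid, epoch2: LandUseGrid, class_code: int) -> np.ndarray:
    """Boolean matrix: True where a cell became ``class_code`` between epochs."""
    epoch1.require_aligned(epoch2)
    unmasked = ~epoch1.nodata_mask
    return (epoch2.values == class_code) & (epoch1.values != class_code) & unmasked


def sample_expansion(
    epoch1: LandUseGrid,
    epoch2: LandUseGrid,
    class_code: int,
    rate: float = 0.01,
    seed: int = 0,
    min_per_side: int = 50,
) -> ExpansionSample:
    """Stratified sample of expansion (positives) vs background (negatives).

    The target total sample size is ``rate`` x unmasked cells, split into
    equal positive and negative halves (balanced classes keep the forest's
    probability output calibrated and chance accuracy at 0.5); each side is
    floored at ``min_per_side`` and capped by availability, so scarce
    expansion shrinks the whole sample rather than unbalancing it.
    """
    rng = np.random.default_rng(seed)
    expansion = extract_expansion(epoch1, epoch2, class_code)
    unmasked = ~epoch1.nodata_mask
    pos_pool = np.flatnonzero(expansion.ravel())
    neg_pool = np.flatnonzero((unmasked & ~expansion).ravel())
    if len(pos_pool) == 0:
        raise ValueError(f"class {class_code}: no expansion cells between epochs")
    target = max(2 * min_per_side, int(rate * unmasked.sum()))
    per_side = max(min_per_side, target // 2)
    n_pos = min(len(pos_pool), per_side)
    n_neg = min(len(neg_pool), max(min_per_side, n_pos))
    pos = rng.choice(pos_pool, size=n_pos, replace=False)
    neg = rng.choice(neg_pool, size=n_neg, replace=False)
    cells = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return ExpansionSample(class_code=class_code, cells=cells, labels=labels, sampling_rate=rate, rng_seed=seed)


def fit_growth_model(
    epoch1: LandUseGrid,
    epoch2: LandUseGrid,
    drivers: DriverStack,
    classes: list[int] | None = None,
    rate: float = 0.01,
    seed: int = 0,
    n_estimators: int = 100,
) -> GrowthProbability:
    """Fit one random forest per class and predict growth probability everywhere.

    Classes with no observed expansion get a zero probability surface with a
    logged notice (nothing to learn from). Fully seeded: identical seeds give
    identical surfaces.
    """
    if not drivers.aligned_with(epoch1):
        raise ValueError("drivers not aligned with land-use grid")
    if classes is None:
        classes = epoch1.class_codes()
    unmasked_cells = np.flatnonzero(~epoch1.nodata_mask.ravel())
    X_all = drivers.as_matrix(unmasked_cells)
    prob: dict[int, np.ndarray] = {}
    importances: dict[int, dict[str, float]] = {}
    oob: dict[int, float] = {}
    for j, k in enumerate(classes):
        surface = np.zeros(epoch1.shape)
        try:
            sample = sample_expansion(epoch1, epoch2, k, rate=rate, seed=seed + 7919 * j)
        except ValueError:
            logger.info("class %d: no expansion observed; zero growth surface", k)
            importances[k] = {n: 0.0 for n in drivers.names}
            oob[k] = float("nan")
            prob[k] = surface
            continue
        if sample.labels.min() == sample.labels.max():
            raise ValueError(f"class {k}: single-class sample, cannot fit growth model")
        X = drivers.as_matrix(sample.cells)
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            oob_score=True,
            random_state=seed + 7919 * j,
            n_jobs=1,
        )
        rf.fit(X, sample.labels)
        p = rf.predict_proba(X_all)[:, list(rf.classes_).index(1)]
        surface.ravel()[unmasked_cells] = p
        prob[k] = surface
        importances[k] = dict(zip(drivers.names, rf.feature_importances_.tolist()))
        oob[k] = float(rf.oob_score_)
    return GrowthProbability(prob=prob, importances=importances, oob_score=oob)
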