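"""Thresholding, four-class suitability maps, projection and change accounting.

The continuous suitability index P is binarised at the maximum test
sensitivity plus specificity threshold (MTSPS) and further split into four
classes: unsuitable (P <= MTSPS), low (MTSPS < P <= 0.4), medium
(0.4 < P <= 0.6) and high (P > 0.6). Projection onto perturbed-climate
grids clamps variables to their training ranges by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import EnvGrid, InputError
from .maxent import MaxEntResults
from .simulate import SuitabilityMap

logger = logging.getLogger(__name__)

CLASS_NAMES = ["unsuitable", "low", "medium", "high"]
NODATA_CLASS = -1


@dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float
    source: str = "pooled_out_of_fold"

    def to_dict(self) -> dict:
        return {
            "mtsps": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "source": self.source,
        }


@dataclass
class ClassifiedMap:
    geometry: object
    classes: np.ndarray  # int, NODATA_CLASS on nodata cells
    nodata_mask: np.ndarray
    mtsps: float
    bounds: tuple[float, float] = (0.4, 0.6)
    label: str = ""

    def counts(self) -> pd.Series:
        vals = self.classes[~self.nodata_mask]
        return pd.Series(
            {name: int((vals == i).sum()) for i, name in enumerate(CLASS_NAMES)}
        )


@dataclass
class ChangeSummary:
    transition: pd.DataFrame  # 4x4 counts, rows = map a, cols = map b
    counts_a: pd.Series
    counts_b: pd.Series
    label_a: str = "a"
    label_b: str = "b"

    def net_change(self) -> pd.Series:
        return self.counts_b - self.counts_a

    def to_frame(self) -> pd.DataFrame:
        return self.transition


def mtsps_threshold(presence_scores: np.ndarray, background_scores: np.ndarray,
                    source: str = "pooled_out_of_fold") -> ThresholdResult:
    """Smallest threshold maximising sensitivity + specificity.

    Candidates are the unique observed scores; sensitivity(t) = fraction of
    presences scoring >= t, specificity(t) = fraction of background scoring
    < t. The smallest maximiser is returned (the inclusive, surveillance-
    conservative tie-break).
    """
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise InputError("both score lists must be non-empty")
    candidates = np.unique(np.concatenate([pres, back]))
    pres_sorted = np.sort(pres)
    back_sorted = np.sort(back)
    # sens(t) = frac presences >= t ; spec(t) = frac background < t.
    # Maximise with integer counts so exact ties resolve to the smallest
    # candidate instead of drifting on float rounding.
    n_ge = pres.size - np.searchsorted(pres_sorted, candidates, side="left")
    n_lt = np.searchsorted(back_sorted, candidates, side="left")
    total = n_ge * back.size + n_lt * pres.size
    best = int(np.argmax(total))  # argmax returns the first (smallest) maximiser
    return ThresholdResult(float(candidates[best]),
                           float(n_ge[best] / pres.size),
                           float(n_lt[best] / back.size), source=source)


def classify(suit: SuitabilityMap, mtsps: float,
             bounds: tuple[float, float] = (0.4, 0.6), label: str = "") -> ClassifiedMap:
    """Partition P into the four suitability classes.

    Boundary semantics are left-open/right-closed: P equal to MTSPS, 0.4 or
    0.6 falls in the lower class. If MTSPS >= the low/medium bound the low
    class is structurally empty (allowed, logged).
    """
    if not (0.0 <= mtsps <= 1.0):
        raise InputError("MTSPS must lie in [0, 1]")
    lo, hi = bounds
    if mtsps >= lo:
        logger.warning("MTSPS %.4f >= %.2f: the low-suitability class is "
                       "structurally empty", mtsps, lo)
    p = suit.values
    cls = np.full(p.shape, 3, dtype=int)
    cls[p <= hi] = 2
    cls[p <= lo] = 1
    cls[p <= mtsps] = 0
    cls[suit.nodata_mask] = NODATA_CLASS
    return ClassifiedMap(suit.geometry, cls, suit.nodata_mask.copy(), mtsps,
                         bounds=bounds, label=label or suit.label)


def project(results: MaxEntResults, scenario_grid: EnvGrid, transform: str | None = None,
            clamp: bool = True, label: str = "") -> SuitabilityMap:
    """Predict the trained model onto a (possibly perturbed) raster stack."""
    return results.predict_grid(scenario_grid, transform=transform, clamp=clamp,
                                label=label)


def change_summary(a: ClassifiedMap, b: ClassifiedMap,
                   cell_area: np.ndarray | None = None) -> ChangeSummary:
    """4x4 class-transition counts between two classified maps.

    Row and column marginals equal the per-map class counts; the total cell
    count is conserved. ``cell_area`` optionally weights cells (e.g. true
    area per latitude band) — transitions are then reported in area units.
    """
    if a.classes.shape != b.classes.shape or np.any(a.nodata_mask != b.nodata_mask):
        raise InputError("maps must share geometry and nodata mask")
    valid = ~a.nodata_mask
    ca = a.classes[valid]
    cb = b.classes[valid]
    if cell_area is None:
        w = np.ones(ca.size)
    else:
        w = np.asarray(cell_area, dtype=float)[valid]
    mat = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            sel = (ca == i) & (cb == j)
            mat[i, j] = w[sel].sum()
    transition = pd.DataFrame(mat, index=CLASS_NAMES, columns=CLASS_NAMES)
    counts_a = transition.sum(axis=1)
    counts_b = transition.sum(axis=0)
    return ChangeSummary(transition, counts_a, counts_b, a.label or "a", b.label or "b")
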