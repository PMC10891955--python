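"""Occurrence cleaning and background sampling.

The cleaning pipeline mirrors standard presence-only practice: exact
coordinate deduplication, removal of records off the analysis grid or on
nodata cells (the raster mask stands in for the land/sea distinction), and
spatial thinning to at most one record per grid cell. A kernel-density
sampling-bias surface built from the presences can weight background draws
so the background carries the same survey bias as the presences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import EnvGrid, GridGeometry, InputError, OccurrenceSet

logger = logging.getLogger(__name__)


@dataclass
class PrepReport:
    """Counts and dropped records for one cleaning stage."""

    stage: str
    n_input: int
    n_retained: int
    dropped: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_retained + len(self.dropped) == self.n_input

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_dropped": len(self.dropped),
            "dropped": self.dropped,
        }


@dataclass
class BiasSurface:
    """Nonnegative per-cell sampling-effort weights, max-rescaled to 1."""

    geometry: GridGeometry
    weights: np.ndarray
    bandwidth: float
    normalization: str = "max"

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise InputError("bias weights must be nonnegative")
        if not np.any(self.weights > 0):
            raise InputError("bias surface must have at least one positive weight")


def deduplicate(occ: OccurrenceSet) -> tuple[OccurrenceSet, PrepReport]:
    """Collapse exact (lon, lat) duplicates to the first occurrence."""
    seen: set[tuple[float, float]] = set()
    kept, dropped = [], []
    for r in occ.records:
        key = (r.lon, r.lat)
        if key in seen:
            dropped.append({"lon": r.lon, "lat": r.lat, "reason": "duplicate"})
        else:
            seen.add(key)
            kept.append(r)
    out = OccurrenceSet(kept, occ.n_dropped_on_read)
    return out, PrepReport("deduplicate", len(occ), len(kept), dropped)


def mask_filter(occ: OccurrenceSet, grid: EnvGrid) -> tuple[OccurrenceSet, PrepReport]:
    """Drop records that are off-grid or fall on nodata cells.

    Records must have been located (:func:`nichecast.grids.locate_cells`).
    No coordinate repair is attempted; removals are reported.
    """
    kept, dropped = [], []
    for r in occ.records:
        if r.cell is None:
            dropped.append({"lon": r.lon, "lat": r.lat, "reason": "off_grid"})
        elif grid.nodata_mask[r.cell]:
            dropped.append({"lon": r.lon, "lat": r.lat, "reason": "nodata_cell"})
        else:
            kept.append(r)
    out = OccurrenceSet(kept, occ.n_dropped_on_read)
    return out, PrepReport("mask_filter", len(occ), len(kept), dropped)


def thin_one_per_cell(occ: OccurrenceSet, geometry: GridGeometry,
                      seed: int | None = None) -> tuple[OccurrenceSet, PrepReport]:
    """Retain exactly one record per occupied cell, chosen uniformly at random.

    Idempotent: an already-thinned set passes through unchanged.
    """
    rng = np.random.default_rng(seed)
    by_cell: dict[tuple[int, int], list[int]] = {}
    for i, r in enumerate(occ.records):
        if r.cell is None:
            raise InputError("records must be located on the grid before thinning")
        by_cell.setdefault(r.cell, []).append(i)
    keep_idx = set()
    for cell in sorted(by_cell):
        members = by_cell[cell]
        keep_idx.add(members[int(rng.integers(len(members)))] if len(members) > 1 else members[0])
    kept, dropped = [], []
    for i, r in enumerate(occ.records):
        if i in keep_idx:
            kept.append(r)
        else:
            dropped.append({"lon": r.lon, "lat": r.lat, "reason": "cell_duplicate"})
    out = OccurrenceSet(kept, occ.n_dropped_on_read)
    return out, PrepReport("thin_one_per_cell", len(occ), len(kept), dropped)


def silverman_bandwidth(coords: np.ndarray) -> float:
    """Silverman's rule for a 2-d Gaussian KDE, averaged over dimensions."""
    n, d = coords.shape
    sd = coords.std(axis=0, ddof=1) if n > 1 else np.zeros(d)
    factor = (4.0 / (d + 2.0) / n) ** (1.0 / (d + 4.0))
    h = float(np.mean(sd) * factor)
    return h


def kernel_bias_surface(occ: OccurrenceSet, geometry: GridGeometry,
                        bandwidth: float | None = None,
                        nodata_mask: np.ndarray | None = None) -> BiasSurface:
    """Gaussian kernel density of presence cell centers, max-rescaled to 1.

    The kernel sum is evaluated directly (vectorised) at every cell center,
    which stays well-defined for a single record or coincident records where
    a covariance-based KDE would be singular. Bandwidth defaults to
    Silverman's rule on the presence cell-center coordinates, floored at one
    cell size.
    """
    cells = occ.cells()
    if cells.shape[0] == 0:
        raise InputError("no located records to build a bias surface from")
    centers = np.array([geometry.cell_center(r, c) for r, c in cells])
    if bandwidth is None:
        bandwidth = silverman_bandwidth(centers)
    if bandwidth <= 0:
        bandwidth = geometry.cell_size
    gx, gy = geometry.cell_centers()
    dx = gx.ravel()[:, None] - centers[:, 0][None, :]
    dy = gy.ravel()[:, None] - centers[:, 1][None, :]
    dens = np.exp(-0.5 * (dx * dx + dy * dy) / bandwidth**2).sum(axis=1)
    weights = dens.reshape(geometry.shape)
    if nodata_mask is not None:
        weights = np.where(nodata_mask, 0.0, weights)
    top = weights.max()
    if top <= 0:
        raise InputError("bias surface degenerated to zero everywhere")
    return BiasSurface(geometry, weights / top, bandwidth=float(bandwidth))


def sample_background(grid: EnvGrid, n: int, bias: BiasSurface | None = None,
                      seed: int | None = None) -> np.ndarray:
    """Sample ``n`` distinct non-nodata cells, probability proportional to bias.

    Returns a (k, 2) array of (row, col). If ``n`` exceeds the number of
    available cells, all of them are returned with a logged warning.
    """
    if n < 1:
        raise InputError("background size must be >= 1")
    valid = grid.valid_cells()
    if valid.shape[0] == 0:
        raise InputError("grid has no valid cells")
    if bias is not None:
        w = bias.weights[valid[:, 0], valid[:, 1]].astype(float)
        usable = w > 0
        if not usable.any():
            raise InputError("bias surface is zero on every valid cell")
        valid, w = valid[usable], w[usable]
    else:
        w = np.ones(valid.shape[0])
    if n >= valid.shape[0]:
        if n > valid.shape[0]:
            logger.warning(
                "requested %d background cells but only %d available; using all",
                n, valid.shape[0])
        order = np.lexsort((valid[:, 1], valid[:, 0]))
        return valid[order]
    rng = np.random.default_rng(seed)
    idx = rng.choice(valid.shape[0], size=n, replace=False, p=w / w.sum())
    chosen = valid[np.sort(idx)]
    return chosen
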