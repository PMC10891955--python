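"""Synthetic environmental worlds with a planted niche.

Real bioclimatic layers are spatially smooth and strongly cross-correlated;
this module emulates both properties so the whole pipeline (selection,
fitting, validation, projection) can be exercised and verified without any
external rasters. It also ships the reference correlation/contribution
tables for the citrus blackfly (CBF) worked example as packaged CSV
fixtures.

Construction of the fields: per band, white noise is smoothed with a
Gaussian kernel and standardised; the bands are then mixed with the
Cholesky factor of a target correlation matrix and affinely rescaled to
physically plausible units (degrees C, mm). Smoothing perturbs the attained
correlations, so the empirical matrix is returned alongside the grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import EnvGrid, GridGeometry, InputError, OccurrenceRecord, OccurrenceSet

ResponseKind = Literal["plateau_unimodal", "peaked", "saturating", "flat"]


@dataclass(frozen=True)
class Response:
    """One band's contribution to true suitability.

    plateau_unimodal: 1 on [lower, upper], Gaussian tails outside with
      width ``tail_frac`` of the plateau span.
    peaked: Gaussian bump centred at ``peak`` with scale ``width``.
    saturating: smoothstep rise from 0 at value 0 up to 1 at ``lower``,
      flat at 1 beyond (the [lower, upper] range is the stated optimum).
    flat: uninformative (constant 1).
    """

    kind: ResponseKind
    lower: float = 0.0
    upper: float = 0.0
    peak: float = 0.0
    width: float = 1.0
    weight: float = 1.0
    tail_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise InputError("response range must satisfy lower <= upper")
        if not (0 < self.weight <= 1):
            raise InputError("weight must be in (0, 1]")

    def optimum_interval(self, bg_min: float, bg_max: float) -> tuple[float, float]:
        """Value range over which this response is at its maximum.

        For a saturating response the optimum extends from the rise point to
        the top of the observed range; flat responses are optimal everywhere.
        """
        if self.kind == "plateau_unimodal":
            return (self.lower, self.upper)
        if self.kind == "peaked":
            return (self.peak, self.peak)
        if self.kind == "saturating":
            return (self.lower, bg_max)
        return (bg_min, bg_max)

    def __call__(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.kind == "flat":
            return np.ones_like(v)
        if self.kind == "peaked":
            return np.exp(-0.5 * ((v - self.peak) / self.width) ** 2)
        if self.kind == "plateau_unimodal":
            tail = max(self.tail_frac * (self.upper - self.lower), 1e-12)
            below = np.exp(-0.5 * ((v - self.lower) / tail) ** 2)
            above = np.exp(-0.5 * ((v - self.upper) / tail) ** 2)
            return np.where(v < self.lower, below, np.where(v > self.upper, above, 1.0))
        if self.kind == "saturating":
            s = np.clip(v / max(self.lower, 1e-12), 0.0, 1.0)
            return s * s * (3.0 - 2.0 * s)
        raise InputError(f"unknown response kind {self.kind!r}")


@dataclass
class NicheSpec:
    """Planted niche: band name -> response."""

    responses: dict[str, Response]

    def __post_init__(self) -> None:
        if not any(r.kind != "flat" for r in self.responses.values()):
            raise InputError("niche needs at least one non-flat response")


@dataclass(frozen=True)
class ScenarioSpec:
    """Additive warming on temperature-like bands, multiplicative scaling on
    precipitation-like bands."""

    label: str
    additive_delta: dict[str, float] = field(default_factory=dict)
    multiplicative_factor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label:
            raise InputError("scenario label must be non-empty")
        if any(f <= 0 for f in self.multiplicative_factor.values()):
            raise InputError("multiplicative factors must be positive")


@dataclass
class SuitabilityMap:
    geometry: GridGeometry
    values: np.ndarray  # (n_rows, n_cols)
    nodata_mask: np.ndarray
    transform: str = "true"
    label: str = ""

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]


@dataclass
class CorrelationFixture:
    names: list[str]
    matrix: pd.DataFrame
    contributions_initial: pd.Series
    contributions_final: pd.Series


def _smooth_unit_field(shape: tuple[int, int], smoothness: float,
                       rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if smoothness > 0:
        noise = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    sd = noise.std()
    return (noise - noise.mean()) / (sd if sd > 0 else 1.0)


def make_env_grid(
    geometry: GridGeometry,
    band_names: Sequence[str],
    smoothness: float = 4.0,
    target_corr: np.ndarray | None = None,
    band_loc: dict[str, float] | None = None,
    band_scale: dict[str, float] | None = None,
    band_min: dict[str, float] | None = None,
    nodata_border: int = 1,
    seed: int | None = None,
) -> tuple[EnvGrid, pd.DataFrame]:
    """Generate correlated smooth bands; returns (grid, achieved correlations).

    ``target_corr`` must be symmetric PSD with unit diagonal; identity when
    omitted. ``band_loc``/``band_scale`` shift and scale each standardised
    band into physical units. ``nodata_border`` masks that many outer
    rows/columns to emulate unusable cells (a coastline stand-in).
    """
    if seed is None:
        raise InputError("seed is mandatory for synthetic generation")
    names = list(band_names)
    k = len(names)
    if target_corr is None:
        target_corr = np.eye(k)
    target_corr = np.asarray(target_corr, dtype=float)
    if target_corr.shape != (k, k) or not np.allclose(target_corr, target_corr.T, atol=1e-10):
        raise InputError("target_corr must be a symmetric k x k matrix")
    if not np.allclose(np.diag(target_corr), 1.0, atol=1e-10):
        raise InputError("target_corr must have unit diagonal")
    eigmin = float(np.linalg.eigvalsh(target_corr).min())
    if eigmin < -1e-8:
        raise InputError(
            "target_corr is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g}); project it to the nearest PSD "
            "correlation matrix first"
        )
    rng = np.random.default_rng(seed)
    fields = np.stack([_smooth_unit_field(geometry.shape, smoothness, rng) for _ in range(k)])
    chol = np.linalg.cholesky(target_corr + 1e-10 * np.eye(k))
    mixed = np.einsum("ij,jrc->irc", chol, fields)
    # restandardise, then place into physical units
    flat = mixed.reshape(k, -1)
    flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(axis=1, keepdims=True)
    mixed = flat.reshape(k, *geometry.shape)
    band_loc = band_loc or {}
    band_scale = band_scale or {}
    band_min = band_min or {}
    for i, name in enumerate(names):
        mixed[i] = band_loc.get(name, 0.0) + band_scale.get(name, 1.0) * mixed[i]
        if name in band_min:
            mixed[i] = np.maximum(mixed[i], band_min[name])
    mask = np.zeros(geometry.shape, dtype=bool)
    if nodata_border > 0:
        mask[:nodata_border, :] = True
        mask[-nodata_border:, :] = True
        mask[:, :nodata_border] = True
        mask[:, -nodata_border:] = True
    mixed[:, mask] = 0.0
    grid = EnvGrid(geometry, names, mixed, mask)
    achieved = pd.DataFrame(
        np.corrcoef(grid.values[:, ~mask]), index=names, columns=names
    )
    return grid, achieved


def true_suitability(grid: EnvGrid, niche: NicheSpec) -> SuitabilityMap:
    """Ground-truth suitability: weighted product of responses, max-rescaled."""
    suit = np.ones(grid.geometry.shape)
    for name, resp in niche.responses.items():
        suit *= resp(grid.band(name)) ** resp.weight
    suit[grid.nodata_mask] = 0.0
    top = suit[~grid.nodata_mask].max()
    if top > 0:
        suit = suit / top
    return SuitabilityMap(grid.geometry, suit, grid.nodata_mask.copy(), transform="true")


def sample_occurrences(
    suit: SuitabilityMap,
    n: int,
    bias_surface: np.ndarray | None = None,
    seed: int | None = None,
    replace: bool = False,
) -> OccurrenceSet:
    """Draw presence cells with probability proportional to suitability x bias.

    Without replacement by default (at most one presence per cell, matching
    the thinned-record world the model is trained on); ``replace=True``
    enables frequency checks against the sampling law.
    """
    if seed is None:
        raise InputError("seed is mandatory for synthetic sampling")
    weights = suit.values.astype(float).copy()
    weights[suit.nodata_mask] = 0.0
    if bias_surface is not None:
        weights = weights * np.asarray(bias_surface, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise InputError("suitability x bias is zero everywhere")
    flat = weights.ravel() / total
    n_available = int(np.count_nonzero(flat))
    if not replace and n > n_available:
        raise InputError(f"cannot draw {n} distinct cells from {n_available} with positive weight")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=replace, p=flat)
    records = []
    for i in idx:
        row, col = divmod(int(i), suit.geometry.n_cols)
        x, y = suit.geometry.cell_center(row, col)
        records.append(OccurrenceRecord(x, y, "synthetic", cell=(row, col)))
    return OccurrenceSet(records)


def apply_scenario(grid: EnvGrid, scenario: ScenarioSpec) -> EnvGrid:
    """Perturb named bands; geometry and mask are unchanged."""
    unknown = (set(scenario.additive_delta) | set(scenario.multiplicative_factor)) \
        - set(grid.band_names)
    if unknown:
        raise InputError(f"scenario names unknown bands: {sorted(unknown)}")
    out = grid.copy()
    for name, delta in scenario.additive_delta.items():
        b = out.band_names.index(name)
        out.values[b, ~out.nodata_mask] += delta
    for name, factor in scenario.multiplicative_factor.items():
        b = out.band_names.index(name)
        out.values[b, ~out.nodata_mask] *= factor
    return out


# ---------------------------------------------------------------------------
# Reference fixture tables (CBF worked example)
# ---------------------------------------------------------------------------

def _fixture_text(name: str) -> str:
    return resources.files("nichecast.fixtures").joinpath(name).read_text(encoding="utf-8")


_EXPECTED_SHA = {
    "cbf_pearson_matrix.csv":
        "aa15694fbb116f5c62eb8e6ea97c242fd3fa1d35c50e4d2886de70c9fc158f87",
    "cbf_contributions_initial.csv":
        "5211ca04f7c0d78660b6e729cbd5d5ad9f0241a3fa6a4467f37b0b896f1a6295",
    "cbf_contributions_final.csv":
        "c46e974089b4de3cc6b4e70dc853460d5dd02e760e79bfdbc7f4506fd5c4b637",
}


def load_reference_tables() -> CorrelationFixture:
    """Load the packaged CBF reference tables.

    Returns the 20-variable pairwise Pearson matrix computed at the presence
    records of the worldwide citrus blackfly dataset, plus the initial-model
    and final-model percent-contribution tables, exactly as published.
    Fixture integrity is checked against frozen SHA-256 digests.
    """
    frames = {}
    for name, expected in _EXPECTED_SHA.items():
        text = _fixture_text(name)
        digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
        if digest != expected:
            raise InputError(f"fixture {name} failed its integrity check")
        frames[name] = text
    import io

    matrix = pd.read_csv(io.StringIO(frames["cbf_pearson_matrix.csv"]), index_col=0)
    init = pd.read_csv(io.StringIO(frames["cbf_contributions_initial.csv"]))
    final = pd.read_csv(io.StringIO(frames["cbf_contributions_final.csv"]))
    if not np.allclose(matrix.values, matrix.values.T):
        raise InputError("fixture correlation matrix is not symmetric")
    if not np.allclose(np.diag(matrix.values), 1.0):
        raise InputError("fixture correlation matrix diagonal must be 1.00")
    return CorrelationFixture(
        names=list(matrix.columns),
        matrix=matrix,
        contributions_initial=init.set_index("variable")["percent_contribution"],
        contributions_final=final.set_index("variable")["percent_contribution"],
    )


# ---------------------------------------------------------------------------
# The default synthetic world
# ---------------------------------------------------------------------------

DEFAULT_BANDS = [
    "temp_cold_q", "prec_wet_m", "prec_dry_m", "temp_mean",
    "temp_seasonality", "prec_annual", "isothermality", "elevation",
]

# moderately correlated bands, echoing the strong temperature/precipitation
# blocks seen in real bioclimatic stacks
_DEFAULT_CORR = np.array([
    # tcq   pwm   pdm   tme   tse   pan   iso   ele
    [1.00, 0.30, 0.10, 0.80, -0.40, 0.25, 0.45, -0.35],
    [0.30, 1.00, 0.35, 0.25, -0.20, 0.85, 0.20, -0.15],
    [0.10, 0.35, 1.00, 0.05, -0.25, 0.45, 0.10, -0.10],
    [0.80, 0.25, 0.05, 1.00, -0.30, 0.20, 0.40, -0.45],
    [-0.40, -0.20, -0.25, -0.30, 1.00, -0.25, -0.60, 0.20],
    [0.25, 0.85, 0.45, 0.20, -0.25, 1.00, 0.15, -0.10],
    [0.45, 0.20, 0.10, 0.40, -0.60, 0.15, 1.00, -0.20],
    [-0.35, -0.15, -0.10, -0.45, 0.20, -0.10, -0.20, 1.00],
])

# Band placement emulates a global-scale climate spread: the cold-quarter
# temperature runs from polar to tropical values so the 15-25 degree niche
# plateau is a restricted warm fraction; precipitation bands are floored at
# zero (arid cells exist, where the dry-month response forces suitability
# to zero).
DEFAULT_BAND_LOC = {
    "temp_cold_q": 5.0, "prec_wet_m": 250.0, "prec_dry_m": 60.0,
    "temp_mean": 12.0, "temp_seasonality": 40.0, "prec_annual": 1000.0,
    "isothermality": 50.0, "elevation": 600.0,
}
DEFAULT_BAND_SCALE = {
    "temp_cold_q": 13.0, "prec_wet_m": 180.0, "prec_dry_m": 70.0,
    "temp_mean": 10.0, "temp_seasonality": 15.0, "prec_annual": 600.0,
    "isothermality": 12.0, "elevation": 400.0,
}
DEFAULT_BAND_MIN = {"prec_wet_m": 0.0, "prec_dry_m": 0.0, "prec_annual": 0.0,
                    "elevation": 0.0}

TEMPERATURE_BANDS = ["temp_cold_q", "temp_mean", "temp_seasonality"]
PRECIPITATION_BANDS = ["prec_wet_m", "prec_dry_m", "prec_annual"]


def default_niche() -> NicheSpec:
    """Planted niche mirroring the CBF response shapes: a thermal plateau at
    15-25 units, a precipitation peak near 200 units, and a saturating
    dry-month response rising over 50-150 units."""
    return NicheSpec({
        "temp_cold_q": Response("plateau_unimodal", lower=15.0, upper=25.0),
        "prec_wet_m": Response("peaked", peak=200.0, width=150.0),
        "prec_dry_m": Response("saturating", lower=50.0, upper=150.0),
    })


def default_scenarios() -> list[ScenarioSpec]:
    """Scenario perturbations spanning mild to strong warming with modest
    precipitation change, labelled after the two emission pathways and
    horizons they emulate."""
    specs = []
    for label, delta, factor in [
        ("SSP1-2.6-2030", 1.0, 1.03),
        ("SSP1-2.6-2050", 2.0, 1.05),
        ("SSP5-8.5-2030", 1.5, 1.04),
        ("SSP5-8.5-2050", 3.0, 0.95),
    ]:
        specs.append(ScenarioSpec(
            label=label,
            additive_delta={b: delta for b in TEMPERATURE_BANDS if b != "temp_seasonality"},
            multiplicative_factor={b: factor for b in PRECIPITATION_BANDS},
        ))
    return specs


def default_world(seed: int, n_rows: int = 100, n_cols: int = 100,
                  n_presences: int = 300) -> tuple[EnvGrid, NicheSpec, SuitabilityMap, OccurrenceSet]:
    """Generate the standard desk-scale study system.

    100x100 grid, 8 correlated bands in physical units, the planted CBF-like
    niche, and presences sampled proportionally to true suitability.
    """
    geometry = GridGeometry(n_rows=n_rows, n_cols=n_cols, x_origin=0.0,
                            y_origin=float(n_rows), cell_size=1.0, crs_label="synthetic")
    grid, _ = make_env_grid(
        geometry, DEFAULT_BANDS, smoothness=4.0, target_corr=_DEFAULT_CORR,
        band_loc=DEFAULT_BAND_LOC, band_scale=DEFAULT_BAND_SCALE,
        band_min=DEFAULT_BAND_MIN, nodata_border=1, seed=seed,
    )
    niche = default_niche()
    suit = true_suitability(grid, niche)
    occ = sample_occurrences(suit, n_presences, seed=seed + 1)
    return grid, niche, suit, occ
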