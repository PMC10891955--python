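"""Presence-background maximum-entropy model.

The model estimates a distribution q(z) proportional to exp(beta . f(z))
over the background cells, where f are feature expansions (linear,
quadratic, product, threshold, hinge) of the environmental variables.
Training minimises the L1-penalised log loss

    L(beta) = -(1/m) sum_presence eta(x)
              + log sum_background w exp(eta(z))
              + sum_k lambda_k |beta_k|,

with eta = beta . f, per-feature penalty lambda_k = RM * rho(class, m) *
sd_k / sqrt(m) (sd_k the feature's background standard deviation, m the
presence count), by cyclic coordinate descent with an exact soft-threshold
step and backtracking. The regularized training gain is G = -L relative to
the uniform model (beta = 0 gives G = 0), and the gain increase of every
accepted coordinate update is attributed to the updated feature's source
variable — the ledger behind percent contribution.

The public surface follows the model/results convention: build a
:class:`MaxEnt` from presence and background tables (or from an
:class:`~nichecast.grids.EnvGrid` plus occurrences), call :meth:`MaxEnt.fit`,
and use the returned :class:`MaxEntResults` for prediction, contributions
and summaries.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import EnvGrid, InputError, OccurrenceSet
from .simulate import SuitabilityMap

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "product", "threshold", "hinge")

# Minimum presence counts for a feature class under automatic selection,
# following the conventional maxent defaults.
AUTO_FEATURE_CUTOFFS = {"linear": 0, "quadratic": 10, "hinge": 15,
                        "threshold": 80, "product": 80}

# Per-class base regularization rho as a piecewise-linear function of the
# presence count (conventional defaults; hinge is constant 0.5).
_RHO_TABLES = {
    "linear": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "quadratic": [(0, 1.3), (10, 0.8), (17, 0.5), (30, 0.25), (100, 0.05)],
    "product": [(0, 2.6), (10, 1.6), (17, 1.0), (30, 1.0), (100, 1.0)],
    "threshold": [(0, 2.0), (100, 1.0)],
}


def _rho(feature_class: str, m: int) -> float:
    if feature_class == "hinge":
        return 0.5
    pts = _RHO_TABLES[feature_class]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return float(np.interp(m, xs, ys))


@dataclass(frozen=True)
class FeatureDef:
    """One basis function over [0,1]-scaled variables."""

    kind: str  # linear | quadratic | product | threshold | hinge
    var: int
    var2: int | None = None  # product partner
    knot: float | None = None  # threshold/hinge, in scaled units
    reverse: bool = False  # hinge orientation

    def label(self, names: Sequence[str]) -> str:
        if self.kind == "linear":
            return names[self.var]
        if self.kind == "quadratic":
            return f"{names[self.var]}^2"
        if self.kind == "product":
            return f"{names[self.var]}*{names[self.var2]}"
        if self.kind == "threshold":
            return f"({names[self.var]}>{self.knot:.3g})"
        arrow = "rev" if self.reverse else "fwd"
        return f"hinge_{arrow}({names[self.var]},{self.knot:.3g})"


@dataclass
class MaxEntConfig:
    """Training configuration.

    ``rm`` is the global regularization multiplier (1 is the field's
    default); ``auto_features`` drops feature classes below the conventional
    presence-count cutoffs; ``n_knots`` sets threshold/hinge knots per
    variable at equally spaced background quantiles.
    """

    feature_classes: tuple[str, ...] = FEATURE_CLASSES
    auto_features: bool = True
    rm: float = 1.0
    n_knots: int = 20
    max_passes: int = 500
    tol: float = 1e-5
    transform: str = "cloglog"
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.rm <= 0:
            raise InputError("regularization multiplier must be positive")
        if self.tol <= 0:
            raise InputError("convergence tolerance must be positive")
        if self.n_knots < 1:
            raise InputError("need at least one knot per variable")
        unknown = set(self.feature_classes) - set(FEATURE_CLASSES)
        if unknown:
            raise InputError(f"unknown feature classes: {sorted(unknown)}")

    def active_classes(self, m: int) -> tuple[str, ...]:
        if not self.auto_features:
            return self.feature_classes
        return tuple(c for c in self.feature_classes if m >= AUTO_FEATURE_CUTOFFS[c])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_classes"] = list(self.feature_classes)
        return d


@dataclass
class FeatureSet:
    """Expanded design matrices plus the scaling that produced them."""

    defs: list[FeatureDef]
    presence: np.ndarray  # (m, K)
    background: np.ndarray  # (n, K)
    var_names: list[str]
    var_min: np.ndarray
    var_max: np.ndarray


def _scale(values: np.ndarray, vmin: np.ndarray, vmax: np.ndarray) -> np.ndarray:
    span = vmax - vmin
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (values - vmin) / np.where(span > 0, span, 1.0)
    return np.clip(np.where(span > 0, scaled, 0.0), 0.0, 1.0)


def _expand(scaled: np.ndarray, defs: list[FeatureDef]) -> np.ndarray:
    cols = np.empty((scaled.shape[0], len(defs)))
    for j, d in enumerate(defs):
        v = scaled[:, d.var]
        if d.kind == "linear":
            cols[:, j] = v
        elif d.kind == "quadratic":
            cols[:, j] = v * v
        elif d.kind == "product":
            cols[:, j] = v * scaled[:, d.var2]
        elif d.kind == "threshold":
            cols[:, j] = (v > d.knot).astype(float)
        elif d.kind == "hinge":
            if d.reverse:
                cols[:, j] = np.maximum(0.0, (d.knot - v) / d.knot) if d.knot > 0 else 0.0
            else:
                cols[:, j] = np.maximum(0.0, (v - d.knot) / (1.0 - d.knot)) if d.knot < 1 \
                    else 0.0
    return cols


def build_features(presence_values: np.ndarray, background_values: np.ndarray,
                   var_names: Sequence[str], config: MaxEntConfig) -> FeatureSet:
    """Scale variables by background min/max and expand the feature basis.

    Knots are placed at equally spaced quantiles of the scaled background
    distribution; duplicate knots (discrete data) are collapsed. A constant
    variable contributes only zero features and a warning.
    """
    presence_values = np.atleast_2d(np.asarray(presence_values, dtype=float))
    background_values = np.atleast_2d(np.asarray(background_values, dtype=float))
    var_names = list(var_names)
    n_vars = len(var_names)
    if background_values.shape[1] != n_vars or presence_values.shape[1] != n_vars:
        raise InputError("value tables and var_names disagree on variable count")
    m = presence_values.shape[0]
    vmin = background_values.min(axis=0)
    vmax = background_values.max(axis=0)
    for i, name in enumerate(var_names):
        if vmin[i] == vmax[i]:
            warnings.warn(f"variable {name!r} is constant over the background; "
                          "it contributes only zero features")
    sp = _scale(presence_values, vmin, vmax)
    sb = _scale(background_values, vmin, vmax)
    classes = config.active_classes(m)
    defs: list[FeatureDef] = []
    for i in range(n_vars):
        if "linear" in classes:
            defs.append(FeatureDef("linear", i))
        if "quadratic" in classes:
            defs.append(FeatureDef("quadratic", i))
    if "product" in classes:
        for i in range(n_vars):
            for j in range(i + 1, n_vars):
                defs.append(FeatureDef("product", i, var2=j))
    if "threshold" in classes or "hinge" in classes:
        qs = np.linspace(0, 1, config.n_knots + 2)[1:-1]
        for i in range(n_vars):
            knots = np.unique(np.round(np.quantile(sb[:, i], qs), 12))
            knots = knots[(knots > 0.0) & (knots < 1.0)]
            for knot in knots:
                if "threshold" in classes:
                    defs.append(FeatureDef("threshold", i, knot=float(knot)))
                if "hinge" in classes:
                    defs.append(FeatureDef("hinge", i, knot=float(knot)))
                    defs.append(FeatureDef("hinge", i, knot=float(knot), reverse=True))
    return FeatureSet(defs, _expand(sp, defs), _expand(sb, defs), var_names, vmin, vmax)


def _soft(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def fit_penalized(
    f_presence: np.ndarray,
    f_background: np.ndarray,
    weights: np.ndarray | None,
    lam: np.ndarray,
    max_passes: int = 500,
    tol: float = 1e-5,
) -> dict:
    """Cyclic coordinate descent on the penalised maxent log loss.

    Exposed separately from the feature machinery so that tiny hand-built
    design matrices can be optimised and compared against brute-force
    minimisation. Returns betas, the per-update gain ledger (feature index
    -> accumulated gain), the per-pass objective trace, and convergence
    metadata.
    """
    f_presence = np.atleast_2d(np.asarray(f_presence, dtype=float))
    f_background = np.atleast_2d(np.asarray(f_background, dtype=float))
    n, k = f_background.shape
    if f_presence.shape[0] < 1 or n < 2:
        raise InputError("need >= 1 presence and >= 2 background samples")
    if not (np.all(np.isfinite(f_presence)) and np.all(np.isfinite(f_background))):
        raise InputError("features must be finite")
    if weights is None:
        weights = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    lam = np.asarray(lam, dtype=float)
    logw = np.log(np.where(weights > 0, weights, 1e-300))
    fbar = f_presence.mean(axis=0)
    fb2 = f_background**2

    beta = np.zeros(k)
    eta = np.zeros(n)
    shifted = np.exp(logw - logw.max())
    log_z = float(logw.max() + np.log(shifted.sum()))
    p = shifted / shifted.sum()
    state = {"penalty": 0.0, "obj": 0.0, "eta": eta, "p": p, "log_z": log_z}
    gain_by_feature = np.zeros(k)
    trace = [0.0]
    updatable = np.isfinite(lam) & (np.ptp(f_background, axis=0) + np.ptp(f_presence, axis=0) > 0)
    all_coords = np.flatnonzero(updatable)

    def _sweep(coords: np.ndarray) -> float:
        """One pass over the given coordinates; returns objective decrease."""
        obj_start = state["obj"]
        for j in coords:
            col = f_background[:, j]
            p_cur = state["p"]
            ef = float(p_cur @ col)
            ef2 = float(p_cur @ fb2[:, j])
            h = max(ef2 - ef * ef, 1e-12)
            g = -fbar[j] + ef
            new_b = _soft(h * beta[j] - g, lam[j]) / h
            delta = new_b - beta[j]
            if abs(delta) < 1e-13:
                continue
            for _ in range(40):
                b_try = beta[j] + delta
                z = state["eta"] + delta * col + logw
                zmax = z.max()
                ez = np.exp(z - zmax)
                s = ez.sum()
                log_z_try = float(zmax + np.log(s))
                pen_try = state["penalty"] + lam[j] * (abs(b_try) - abs(beta[j]))
                obj_try = -(beta @ fbar + delta * fbar[j]) + log_z_try + pen_try
                if obj_try <= state["obj"] + 1e-12:
                    gain_by_feature[j] += state["obj"] - obj_try
                    beta[j] = b_try
                    state["eta"] = z - logw
                    state["log_z"] = log_z_try
                    state["penalty"] = pen_try
                    state["p"] = ez / s
                    state["obj"] = obj_try
                    break
                delta *= 0.5
                if abs(delta) < 1e-13:
                    break
        return obj_start - state["obj"]

    converged = False
    n_passes = 0
    while n_passes < max_passes:
        n_passes += 1
        full_decrease = _sweep(all_coords)
        trace.append(-state["obj"])
        if full_decrease < tol:
            converged = True
            break
        # glmnet-style: iterate the active (nonzero) set to convergence
        # before the next full sweep over all coordinates
        while n_passes < max_passes:
            active = np.flatnonzero((beta != 0) & updatable)
            if active.size == 0:
                break
            n_passes += 1
            decrease = _sweep(active)
            trace.append(-state["obj"])
            if decrease < tol:
                break
    if not converged:
        warnings.warn(f"coordinate descent did not converge in {max_passes} passes")
    eta = state["eta"]
    log_z = state["log_z"]
    p = state["p"]
    obj = state["obj"]
    entropy = float(-(p * np.log(np.where(p > 0, p, 1.0))).sum())
    return {
        "beta": beta,
        "log_z": log_z,
        "entropy": entropy,
        "gain": -obj,
        "gain_by_feature": gain_by_feature,
        "gain_trace": trace,
        "converged": converged,
        "n_passes": n_passes,
        "weights": weights,
    }


class MaxEnt:
    """Presence-background maximum-entropy model.

    Parameters
    ----------
    presence, background : array-like or DataFrame, shape (m, V) / (n, V)
        Raw (unscaled) environmental values at presence sites and background
        cells.
    var_names : sequence of str, optional
        Variable names; taken from DataFrame columns when omitted.
    background_weights : array, optional
        Nonnegative sampling-bias weights for the background cells.
    config : MaxEntConfig, optional
    """

    def __init__(self, presence, background, var_names: Sequence[str] | None = None,
                 background_weights: np.ndarray | None = None,
                 config: MaxEntConfig | None = None) -> None:
        if isinstance(presence, pd.DataFrame):
            var_names = var_names or list(presence.columns)
            presence = presence.to_numpy(dtype=float)
        if isinstance(background, pd.DataFrame):
            var_names = var_names or list(background.columns)
            background = background.to_numpy(dtype=float)
        self.presence = np.atleast_2d(np.asarray(presence, dtype=float))
        self.background = np.atleast_2d(np.asarray(background, dtype=float))
        if var_names is None:
            var_names = [f"x{i}" for i in range(self.presence.shape[1])]
        self.var_names = list(var_names)
        self.background_weights = background_weights
        self.config = config or MaxEntConfig()
        if self.presence.shape[0] < 1:
            raise InputError("need at least one presence record")
        if self.background.shape[0] < 2:
            raise InputError("need at least two background samples")

    @classmethod
    def from_env_grid(cls, grid: EnvGrid, occ: OccurrenceSet,
                      variables: Sequence[str] | None = None,
                      background_cells: np.ndarray | None = None,
                      background_weights: np.ndarray | None = None,
                      config: MaxEntConfig | None = None) -> "MaxEnt":
        """Build from a raster stack plus located occurrences.

        Background defaults to every valid cell of the grid.
        """
        variables = list(variables) if variables is not None else list(grid.band_names)
        sub = grid.subset(variables)
        cells = occ.cells()
        if cells.shape[0] == 0:
            raise InputError("no located presence records")
        presence = sub.table_at(cells[:, 0], cells[:, 1])
        if background_cells is None:
            background_cells = sub.valid_cells()
        background = sub.table_at(background_cells[:, 0], background_cells[:, 1])
        return cls(presence, background, var_names=variables,
                   background_weights=background_weights, config=config)

    @property
    def n_presence(self) -> int:
        return self.presence.shape[0]

    def penalties(self, features: FeatureSet) -> np.ndarray:
        """lambda_k = RM * rho(class, m) * sd_k / sqrt(m), infinite for
        constant features (never updated)."""
        m = self.n_presence
        sd = features.background.std(axis=0)
        lam = np.empty(len(features.defs))
        for j, d in enumerate(features.defs):
            if sd[j] <= 0:
                lam[j] = np.inf
            else:
                lam[j] = self.config.rm * _rho(d.kind, m) * sd[j] / np.sqrt(m)
        return lam

    def fit(self, seed: int | None = None) -> "MaxEntResults":
        features = build_features(self.presence, self.background, self.var_names, self.config)
        lam = self.penalties(features)
        state = fit_penalized(
            features.presence, features.background, self.background_weights, lam,
            max_passes=self.config.max_passes, tol=self.config.tol,
        )
        return MaxEntResults(self, features, lam, state, seed=seed)


class MaxEntResults:
    """Fitted model: coefficients, gain ledger, prediction and reporting."""

    def __init__(self, model: MaxEnt, features: FeatureSet, lam: np.ndarray,
                 state: dict, seed: int | None = None) -> None:
        self.model = model
        self.features = features
        self.lam = lam
        self.params = state["beta"]
        self.log_z = state["log_z"]
        self.entropy = state["entropy"]
        self.gain = state["gain"]
        self.gain_by_feature = state["gain_by_feature"]
        self.gain_trace = state["gain_trace"]
        self.converged = state["converged"]
        self.n_passes = state["n_passes"]
        self.background_weights = state["weights"]
        self.seed = seed
        self.presence_means = model.presence.mean(axis=0)

    # -- prediction ---------------------------------------------------------

    def _eta(self, values: np.ndarray, clamp: bool | None = None) -> np.ndarray:
        clamp = self.model.config.clamp if clamp is None else clamp
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if clamp:
            values = np.clip(values, self.features.var_min, self.features.var_max)
        scaled = _scale(values, self.features.var_min, self.features.var_max)
        return _expand(scaled, self.features.defs) @ self.params

    def predict_values(self, values: np.ndarray, transform: str | None = None,
                       clamp: bool | None = None) -> np.ndarray:
        """Predict at raw variable rows (V columns, model variable order).

        ``raw`` treats each point as carrying uniform reference mass 1/n
        over the training background; ``cloglog`` (default) and ``logistic``
        rescale raw through the training-distribution entropy H so values
        fall in [0, 1].
        """
        transform = transform or self.model.config.transform
        eta = self._eta(values, clamp=clamp)
        n = self.model.background.shape[0]
        raw = np.exp(eta - self.log_z) / n
        if transform == "raw":
            return raw
        r = np.exp(self.entropy) * raw
        if transform == "cloglog":
            return 1.0 - np.exp(-r)
        if transform == "logistic":
            return r / (1.0 + r)
        raise InputError(f"unknown transform {transform!r}")

    def predict_grid(self, grid: EnvGrid, transform: str | None = None,
                     clamp: bool | None = None, label: str = "") -> SuitabilityMap:
        """Predict over every valid cell of an aligned raster stack."""
        missing = set(self.model.var_names) - set(grid.band_names)
        if missing:
            raise InputError(f"grid is missing model variables: {sorted(missing)}")
        sub = grid.subset(self.model.var_names)
        cells = sub.valid_cells()
        vals = sub.table_at(cells[:, 0], cells[:, 1]).to_numpy()
        pred = self.predict_values(vals, transform=transform, clamp=clamp)
        out = np.zeros(grid.geometry.shape)
        out[cells[:, 0], cells[:, 1]] = pred
        return SuitabilityMap(grid.geometry, out, grid.nodata_mask.copy(),
                              transform=transform or self.model.config.transform,
                              label=label)

    def raw_on_background(self) -> np.ndarray:
        """Raw probability of each training background cell (sums to 1)."""
        eta = self.features.background @ self.params
        return self.background_weights * np.exp(eta - self.log_z)

    # -- reporting ----------------------------------------------------------

    def percent_contribution(self) -> pd.Series:
        """Per-variable share of accumulated training-gain increments,
        normalised to sum to 100 (product features split evenly between
        their two source variables)."""
        acc = np.zeros(len(self.model.var_names))
        for j, d in enumerate(self.features.defs):
            g = max(self.gain_by_feature[j], 0.0)
            if d.kind == "product":
                acc[d.var] += g / 2.0
                acc[d.var2] += g / 2.0
            else:
                acc[d.var] += g
        total = acc.sum()
        if total <= 0:
            warnings.warn("no positive gain accumulated; contributions are all zero")
            pct = acc
        else:
            pct = 100.0 * acc / total
        return pd.Series(pct, index=self.model.var_names).sort_values(ascending=False)

    def summary(self) -> str:
        lines = [
            "Maximum-entropy presence-background model",
            "=" * 57,
            f"presences:            {self.model.n_presence}",
            f"background:           {self.model.background.shape[0]}",
            f"variables:            {len(self.model.var_names)}",
            f"features:             {len(self.features.defs)} "
            f"({np.count_nonzero(self.params)} nonzero)",
            f"regularization (RM):  {self.model.config.rm}",
            f"regularized gain:     {self.gain:.4f}",
            f"entropy:              {self.entropy:.4f}",
            f"converged:            {self.converged} ({self.n_passes} passes)",
            "",
            "Percent contribution",
            "-" * 32,
        ]
        for name, pct in self.percent_contribution().items():
            lines.append(f"{name:<22s} {pct:7.1f}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: Path | str | None = None) -> str:
        doc = {
            "var_names": self.model.var_names,
            "var_min": self.features.var_min.tolist(),
            "var_max": self.features.var_max.tolist(),
            "features": [asdict(d) for d in self.features.defs],
            "beta": self.params.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "gain": self.gain,
            "gain_by_feature": self.gain_by_feature.tolist(),
            "n_background": int(self.model.background.shape[0]),
            "presence_means": self.presence_means.tolist(),
            "config": self.model.config.to_dict(),
            "converged": self.converged,
            "n_passes": self.n_passes,
            "seed": self.seed,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path_or_text: Path | str) -> "MaxEntResults":
        """Rebuild a predictor from a serialized model document.

        The restored object reproduces predictions bit-for-bit; the training
        matrices themselves are not stored, so refitting and
        background-level diagnostics are unavailable on a loaded model.
        """
        text = str(path_or_text)
        if not text.lstrip().startswith("{"):
            text = Path(path_or_text).read_text(encoding="utf-8")
        doc = json.loads(text)
        cfg_doc = dict(doc["config"])
        cfg_doc["feature_classes"] = tuple(cfg_doc["feature_classes"])
        config = MaxEntConfig(**cfg_doc)
        n = doc["n_background"]
        model = object.__new__(MaxEnt)
        model.var_names = doc["var_names"]
        model.config = config
        model.presence = np.atleast_2d(np.asarray(doc["presence_means"], dtype=float))
        model.background = np.empty((n, len(doc["var_names"])))
        model.background_weights = None
        features = FeatureSet(
            defs=[FeatureDef(**d) for d in doc["features"]],
            presence=np.empty((0, len(doc["features"]))),
            background=np.empty((0, len(doc["features"]))),
            var_names=doc["var_names"],
            var_min=np.asarray(doc["var_min"], dtype=float),
            var_max=np.asarray(doc["var_max"], dtype=float),
        )
        state = {
            "beta": np.asarray(doc["beta"], dtype=float),
            "log_z": doc["log_z"],
            "entropy": doc["entropy"],
            "gain": doc["gain"],
            "gain_by_feature": np.asarray(doc["gain_by_feature"], dtype=float),
            "gain_trace": [],
            "converged": doc["converged"],
            "n_passes": doc["n_passes"],
            "weights": np.full(n, 1.0 / n),
        }
        out = cls(model, features, np.array([]), state, seed=doc.get("seed"))
        out.presence_means = np.asarray(doc["presence_means"], dtype=float)
        return out
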