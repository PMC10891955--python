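"""Model validation: cross-validated AUC, jackknife gains, response curves.

Cross-validation follows presence-background convention: only the presences
are partitioned into folds; the background is shared by every fold. The AUC
is the rank-based (Mann-Whitney) estimator — the probability that a random
presence outscores a random background point, ties counted one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grids import EnvGrid, InputError, OccurrenceSet
from .maxent import MaxEnt, MaxEntConfig, MaxEntResults


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC of presence vs background scores (ties count 0.5)."""
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise InputError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pres, back]))
    r_pres = ranks[: pres.size].sum()
    return float((r_pres - pres.size * (pres.size + 1) / 2.0) / (pres.size * back.size))


@dataclass
class EvaluationReport:
    fold_aucs: list[float]
    fold_results: list[MaxEntResults]
    pooled_presence_scores: np.ndarray  # out-of-fold score of each presence
    background_scores: np.ndarray  # per-cell mean over fold models

    @property
    def k(self) -> int:
        return len(self.fold_aucs)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1)) if self.k > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
        }


@dataclass
class JackknifeResult:
    gain_full: float
    with_only: pd.DataFrame  # index variable, columns mean/sd
    without: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        df = pd.concat(
            {"with_only": self.with_only, "without": self.without}, axis=1
        )
        df.attrs["gain_full"] = self.gain_full
        return df


@dataclass
class ResponseCurve:
    variable: str
    values: np.ndarray  # strictly increasing evaluation grid
    mean: np.ndarray  # mean predicted P across replicate models
    sd: np.ndarray

    @property
    def argmax(self) -> float:
        return float(self.values[int(np.argmax(self.mean))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "mean_p": self.mean, "sd_p": self.sd})


def _fold_indices(m: int, k: int, seed: int | None) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _tables(grid: EnvGrid, occ: OccurrenceSet, variables: Sequence[str]):
    sub = grid.subset(list(variables))
    cells = occ.cells()
    if cells.shape[0] == 0:
        raise InputError("no located presences")
    presence = sub.table_at(cells[:, 0], cells[:, 1]).to_numpy()
    bg_cells = sub.valid_cells()
    background = sub.table_at(bg_cells[:, 0], bg_cells[:, 1]).to_numpy()
    return presence, background


def cross_validate(occ: OccurrenceSet, grid: EnvGrid, variables: Sequence[str],
                   config: MaxEntConfig | None = None, k: int = 10,
                   seed: int | None = None,
                   background: np.ndarray | None = None,
                   background_weights: np.ndarray | None = None) -> EvaluationReport:
    """k-fold cross-validated AUC (folds over presences, shared background).

    The pooled out-of-fold presence scores and the per-cell mean background
    scores feed threshold selection downstream.
    """
    config = config or MaxEntConfig()
    variables = list(variables)
    presence, grid_background = _tables(grid, occ, variables)
    if background is None:
        background = grid_background
    m = presence.shape[0]
    if k > m:
        raise InputError(f"k={k} exceeds the {m} available presences")
    folds = _fold_indices(m, k, seed)
    fold_aucs: list[float] = []
    fold_results: list[MaxEntResults] = []
    pooled = np.empty(m)
    bg_scores = np.zeros(background.shape[0])
    for fold in folds:
        train = np.setdiff1d(np.arange(m), fold)
        model = MaxEnt(presence[train], background, var_names=variables,
                       background_weights=background_weights, config=config)
        res = model.fit(seed=seed)
        test_scores = res.predict_values(presence[fold])
        back_scores = res.predict_values(background)
        fold_aucs.append(auc(test_scores, back_scores))
        fold_results.append(res)
        pooled[fold] = test_scores
        bg_scores += back_scores / k
    return EvaluationReport(fold_aucs, fold_results, pooled, bg_scores)


def jackknife(occ: OccurrenceSet, grid: EnvGrid, variables: Sequence[str],
              config: MaxEntConfig | None = None, k_replicates: int = 5,
              seed: int | None = None) -> JackknifeResult:
    """Per-variable regularized training gain with-only vs without.

    Each replicate re-fits on a k-fold training split (the cross-validation
    replicate convention); gains are averaged over replicates.
    """
    config = config or MaxEntConfig()
    variables = list(variables)
    if len(variables) < 1:
        raise InputError("jackknife needs at least one variable")
    if len(variables) == 1:
        warnings.warn("jackknife with a single variable: the without-model "
                      "is the null model with zero gain")
    presence, background = _tables(grid, occ, variables)
    m = presence.shape[0]
    folds = _fold_indices(m, min(k_replicates, m), seed)
    full_gains = []
    gains_only = {v: [] for v in variables}
    gains_without = {v: [] for v in variables}

    def _gain(cols: list[int], rows: np.ndarray) -> float:
        if not cols:
            return 0.0
        model = MaxEnt(presence[np.ix_(rows, cols)], background[:, cols],
                       var_names=[variables[c] for c in cols], config=config)
        return model.fit().gain

    for fold in folds[:k_replicates]:
        train = np.setdiff1d(np.arange(m), fold)
        full_gains.append(_gain(list(range(len(variables))), train))
        for i, v in enumerate(variables):
            gains_only[v].append(_gain([i], train))
            gains_without[v].append(_gain([j for j in range(len(variables)) if j != i], train))

    def _summ(d: dict[str, list[float]]) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": {v: float(np.mean(g)) for v, g in d.items()},
            "sd": {v: float(np.std(g, ddof=1)) if len(g) > 1 else 0.0 for v, g in d.items()},
        })

    return JackknifeResult(float(np.mean(full_gains)), _summ(gains_only), _summ(gains_without))


def response_curve(results: Sequence[MaxEntResults], variable: str,
                   n_points: int = 100) -> ResponseCurve:
    """Marginal response: vary one variable over its background range with
    the others held at their presence-record means; average over the
    supplied replicate models."""
    if not results:
        raise InputError("need at least one fitted model")
    first = results[0]
    if variable not in first.model.var_names:
        raise InputError(f"unknown variable {variable!r}")
    vi = first.model.var_names.index(variable)
    lo, hi = first.features.var_min[vi], first.features.var_max[vi]
    values = np.linspace(lo, hi, n_points)
    preds = []
    for res in results:
        if variable not in res.model.var_names:
            raise InputError(f"model lacks variable {variable!r}")
        j = res.model.var_names.index(variable)
        table = np.tile(res.presence_means, (n_points, 1))
        table[:, j] = values
        preds.append(res.predict_values(table))
    preds = np.vstack(preds)
    sd = preds.std(axis=0, ddof=1) if preds.shape[0] > 1 else np.zeros(n_points)
    return ResponseCurve(variable, values, preds.mean(axis=0), sd)


def plot_response_curve(curve: ResponseCurve, ax=None):
    """Mean response in red with a +/-1 sd band, the field's usual style."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(curve.values, curve.mean - curve.sd, curve.mean + curve.sd,
                    color="steelblue", alpha=0.4, label="±1 sd")
    ax.plot(curve.values, curve.mean, color="red", label="mean response")
    ax.set_xlabel(curve.variable)
    ax.set_ylabel("predicted suitability P")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
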