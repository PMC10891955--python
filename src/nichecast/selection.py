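"""Two-stage bioclimatic variable selection.

Stage A (collinearity): over all pairs simultaneously, a variable is dropped
iff some *strictly* higher-contribution variable correlates with it at
|r| > r_threshold. The absolute value matters: strong negative correlations
(e.g. a temperature-seasonality variable against a cold-quarter temperature)
must eliminate just like positive ones. Stage B: survivors contributing
<= min_contribution percent in the initial model are dropped.

The all-pairs rule is order-independent by construction; a greedy
sequential elimination is *not* equivalent (it can spare a variable whose
dominating partner was already eliminated) and does not reproduce the
reference worked example.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EnvGrid, InputError, OccurrenceSet


class TieError(InputError):
    """A correlated pair with exactly equal contributions, where the outcome
    depends on an arbitrary tie-break. Demand an explicit decision."""


@dataclass
class SelectionReport:
    kept: list[str]  # ordered by contribution, descending
    dropped: dict[str, dict]  # name -> {reason, partner?, r?, percent?}
    r_threshold: float
    min_contribution: float
    contributions: dict[str, float] = field(default_factory=dict)

    def kept_contributions(self) -> list[float]:
        return [self.contributions[v] for v in self.kept]

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "kept_contributions": self.kept_contributions(),
            "dropped": self.dropped,
            "r_threshold": self.r_threshold,
            "min_contribution": self.min_contribution,
        }


def pearson_at_presences(grid: EnvGrid, occ: OccurrenceSet) -> pd.DataFrame:
    """Pairwise Pearson correlations of the band values at presence cells.

    Computed over presence sites only, not the whole raster. A zero-variance
    variable gets zero off-diagonal entries and a warning.
    """
    cells = occ.cells()
    if cells.shape[0] < 3:
        raise InputError("need at least 3 located presence records")
    table = grid.table_at(cells[:, 0], cells[:, 1])
    sd = table.std(ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        import warnings

        warnings.warn(f"zero variance at presences for {degenerate}; "
                      "their correlations are set to 0")
    corr = table.corr(method="pearson")
    for name in degenerate:
        corr.loc[name, :] = 0.0
        corr.loc[:, name] = 0.0
        corr.loc[name, name] = 1.0
    return corr


def select_variables(corr: pd.DataFrame, contributions: pd.Series | dict,
                     r_threshold: float = 0.7,
                     min_contribution: float = 1.0) -> SelectionReport:
    """Apply the two-stage rule; see module docstring for semantics.

    Both thresholds are strict ("greater than"). Raises :class:`TieError`
    if a violating pair has exactly equal contributions *and* the tie is
    decision-relevant (neither member is dropped by some strictly stronger
    partner anyway).
    """
    contributions = pd.Series(contributions, dtype=float)
    names = list(corr.columns)
    missing = set(names) - set(contributions.index)
    if missing:
        raise InputError(f"missing contribution for: {sorted(missing)}")
    r = corr.loc[names, names].to_numpy(dtype=float)
    if not np.allclose(r, r.T, atol=1e-12):
        raise InputError("correlation matrix must be symmetric")
    c = contributions.loc[names].to_numpy(dtype=float)

    dropped: dict[str, dict] = {}
    for i, v in enumerate(names):
        # the strongest strictly-higher-contribution partner above threshold
        best = None
        for j, u in enumerate(names):
            if j == i or c[j] <= c[i]:
                continue
            if abs(r[i, j]) > r_threshold:
                if best is None or abs(r[i, j]) > abs(r[i, best]):
                    best = j
        if best is not None:
            dropped[v] = {"reason": "correlated", "partner": names[best],
                          "r": float(r[i, best])}
    survivors = [v for v in names if v not in dropped]

    # decision-relevant exact ties among surviving violating pairs
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if abs(r[a, b]) > r_threshold and c[a] == c[b] \
                    and names[a] in survivors and names[b] in survivors:
                raise TieError(
                    f"variables {names[a]!r} and {names[b]!r} are correlated "
                    f"(r={r[a, b]:.2f}) with equal contributions {c[a]}; "
                    "an explicit tie-break is required")

    kept = []
    for v in survivors:
        pct = float(contributions[v])
        if pct > min_contribution:
            kept.append(v)
        else:
            dropped[v] = {"reason": "low_contribution", "percent": pct}
    kept.sort(key=lambda v: (-contributions[v], v))
    return SelectionReport(
        kept=kept,
        dropped=dropped,
        r_threshold=r_threshold,
        min_contribution=min_contribution,
        contributions={v: float(contributions[v]) for v in names},
    )
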