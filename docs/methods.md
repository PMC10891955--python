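# Methods

This note records the modelling choices behind `nichecast`: the estimator,
its tunable parameters, what the synthetic worlds do and do not emulate,
and the numerical conventions that make runs reproducible.

## Presence-background estimator

The core model is a maximum-entropy (Gibbs) density over background cells,
fitted to presence-only records. With features `f` scaled to [0,1] by the
background minimum/maximum of each variable, training minimises

```
L(beta) = -(1/m) sum_presence beta.f(x)
          + log sum_background w exp(beta.f(z))
          + sum_k lambda_k |beta_k|
```

where `w` are normalised background weights (uniform, or a sampling-bias
surface). `L(0) = 0`, so the regularized training gain `G = -L(beta_hat)`
is exactly zero for the null model and non-negative at convergence.

**Feature classes.** Linear and quadratic terms per variable, pairwise
products, step indicators (threshold) and forward/reverse ramps (hinge).
Threshold/hinge knots sit at equally spaced quantiles of the scaled
background distribution (default 20 per variable; duplicates from discrete
data are collapsed). Under automatic feature selection, classes activate
with presence count m: quadratic at 10, hinge at 15, threshold and product
at 80 — the conventional cutoffs for this model family.

**Penalties.** `lambda_k = RM * rho(class, m) * sd_k / sqrt(m)`, with
`sd_k` the feature's background standard deviation and `rho` the
conventional per-class base constants (piecewise-linear in m for
linear/quadratic/product/threshold; hinge fixed at 0.5). These follow the
published defaults of the model family but are not bit-matched to any
particular implementation; `RM` (default 1) rescales all of them. A
constant feature receives an infinite penalty and is never updated.

**Optimizer.** Cyclic coordinate descent with an exact one-dimensional
soft-threshold Newton step and backtracking halving, so the penalised
objective is non-increasing at every accepted update. After each full
sweep the active (nonzero) set is iterated to convergence before the next
full sweep — the usual lasso-path strategy; on the default synthetic
problem this converges in a few hundred sweeps in a few seconds.
Convergence is declared when a full sweep decreases the objective by less
than `tol` (default 1e-5). The per-update gain increments are accumulated
per source variable (product features split evenly between their two
variables) and normalised to the percent-contribution table. This
attribution is exactly why a coordinate-wise optimizer is used: a
full-gradient method would leave per-variable attribution undefined.

**Output transforms.** Raw output treats a query point as carrying uniform
reference mass 1/n against the training background normaliser; over the
training background (uniform weights) raw values sum to one. The default
reported index is the cloglog transform `P = 1 - exp(-exp(H) * raw)` with
`H` the entropy of the fitted background distribution; the logistic
transform is available. Projection onto new grids clamps variables to
their training ranges by default, the standard guard against feature
extrapolation under novel climates.

## Variable selection

Stage A drops a variable iff *some* strictly higher-contribution variable
correlates with it at `|r| > 0.7`, judged over all pairs simultaneously;
stage B drops survivors contributing `<= 1%`. Both thresholds are strict
inequalities, matching the stated rule ("greater than 0.7", "more than
1%"). Two deliberate conventions:

- **Absolute correlation.** `|r|`, not signed r, is compared with the
  threshold. With signed comparison a strongly anti-correlated pair (e.g.
  temperature seasonality against winter temperature at r = -0.96) would
  never be pruned, and the packaged worked example demonstrably fails to
  reproduce its published outcome. A regression test pins this.
- **All-pairs, not greedy.** Greedy elimination in descending contribution
  order can spare a variable whose dominating partner was already removed
  by someone else; the all-pairs rule is order-independent and is the only
  reading that reproduces the reference tables.
- **Ties.** A correlated pair with exactly equal contributions raises an
  error *when the tie is decision-relevant* (neither member is removed by
  a strictly stronger partner anyway); irrelevant ties — which do occur in
  the reference tables — are tolerated, since every resolution yields the
  same kept set. Silent tie-breaking would be invisible nondeterminism.

## Evaluation

- **AUC** is the rank-based (Mann-Whitney) estimator with ties counted
  one-half; it equals the exhaustive over-all-pairs probability that a
  presence outscores a background point, and is invariant to monotone
  transforms of the scores.
- **Cross-validation** partitions only the presences into k seeded,
  balanced folds (default k = 10); the background is shared across folds,
  the convention of this model family. The reported spread is the
  standard deviation across folds. Pooled out-of-fold presence scores and
  per-cell background scores averaged over fold models feed the MTSPS.
- **MTSPS** maximises sensitivity(t) = fraction of presences >= t plus
  specificity(t) = fraction of background < t over the unique observed
  scores, using integer-count arithmetic so exact ties deterministically
  resolve to the *smallest* maximising threshold (the inclusive choice —
  larger suitable area — which is the conservative direction for pest
  surveillance).
- **Jackknife importance** refits with-only and without models per
  replicate training split and averages the regularized gains.
- **Response curves** vary one variable over its background range with the
  others fixed at their presence-record means ("sample" averages in the
  presence-only idiom), averaged across replicate models.

## Classification and change accounting

Class boundaries are left-open/right-closed: `P <= MTSPS` unsuitable,
`MTSPS < P <= 0.4` low, `0.4 < P <= 0.6` medium, `P > 0.6` high. If MTSPS
reaches 0.4 the low class is structurally empty; this is logged, not
fatal. Change summaries between two classified maps are 4x4 transition
counts whose marginals equal the per-map class totals (cell counts, or
area units when per-cell weights are supplied).

## Synthetic worlds

`make_env_grid` builds each band as Gaussian-smoothed white noise
(standardised), mixes bands with the Cholesky factor of a target
correlation matrix, and rescales to physical units. Smoothing perturbs the
attained correlations, so the empirical matrix is returned alongside the
grid and used by downstream selection tests. The default world is a
100x100 grid of 8 bands with temperature/precipitation-style correlation
blocks, a one-cell nodata border, and precipitation bands floored at zero.

The planted niche multiplies three responses: a plateau at 15–25 units on
the cold-quarter temperature (Gaussian tails of width 20% of the plateau
span — the reference analysis reports shapes, not formulas), a Gaussian
peak at 200 units (width 150) on wet-month precipitation, and a smoothstep
saturating rise to 50 units on dry-month precipitation (zero suitability
at zero precipitation). Band placement emulates a global-scale climate
spread, so the niche occupies a restricted warm fraction of the landscape
(~10% of cells above suitability 0.5); that selectivity is what puts
cross-validated AUC in the elevated-performance band (~0.92–0.94 across
seeds) comparable to the reference analysis. Presences (default 300,
roughly the scale of the cleaned reference dataset) are drawn without
replacement proportionally to true suitability; a bias surface can
distort the draw to emulate uneven survey effort.

What the synthetic worlds do *not* emulate: spherical geometry and
latitude-dependent cell area, coastline/ocean masks beyond a border,
temporal autocorrelation of climate normals, real CMIP6 scenario structure
(scenarios are simple additive warming and multiplicative precipitation
scaling), and observer-driven taxonomic error. Passing tests therefore
demonstrate algorithmic correctness and statistical behaviour under
controlled conditions, not transferability to any particular real
landscape.

## Problem sizes and numerical conventions

Default desk-scale sizes: 100x100 grid (~9.6k valid cells, all used as
background when the requested 10,000 exceeds availability), 300 presences,
k = 10 folds, 3–5 jackknife replicates, 20 knots per variable. A full
pipeline run completes in roughly half a minute on one CPU; the heavier
statistical checks (ten seeds of 10-fold cross-validation) take a couple
of minutes. All stochastic stages require explicit seeds; the pipeline
derives per-stage seeds from one master seed by labelled SHA-256 hashing,
so enabling or disabling one stage never shifts another's random stream,
and repeated runs are byte-identical on JSON/CSV artifacts. Grid cells use
the half-open `[edge, edge + cell_size)` convention with row 0 at the
north; ESRI ASCII grids are the bit-exact interchange format (TIFF with an
ESRI world file is supported for convenience; CRS handling and
reprojection are out of scope). The packaged reference tables are
integrity-checked against frozen SHA-256 digests at load.

## Known limitations

- Percent contribution is path-dependent (as in the model family it
  mirrors): it depends on the coordinate-update order and is meaningful as
  a relative, not absolute, measure.
- The bias-surface KDE uses one isotropic bandwidth (Silverman default);
  strongly anisotropic survey effort is not represented.
- Loaded (deserialized) models reproduce predictions exactly but do not
  carry training matrices, so refitting and background diagnostics require
  the original data.
- `RM` monotonicity of the L1 path is verified empirically on small
  instances; it is not a theorem for arbitrary designs.
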