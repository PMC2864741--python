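# Methods

This note documents the statistical machinery the package implements, the
defaults it ships, and the choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Rasters and geometry

The spatial currency is a row-major raster (northernmost row first) with
a nodata sentinel, georeferenced by lower-left corner and square cell
size in degrees, read and written as ESRI ASCII. Coordinates are treated
as planar everywhere: the synthetic worlds are abstract, and neither
reprojection nor great-circle distance is attempted. Point-in-cell
assignment uses half-open cells — [x, x+cs) in longitude, (y, y+cs] in
latitude — so a point on a shared edge deterministically belongs to the
cell to its east/south. ASCII output defaults to the shortest exactly
round-trippable decimal per value, making write→read bit-exact; a
significant-digits mode is available when smaller files matter more than
exactness.

## Maximum-entropy niche model

The model is the Gibbs distribution over a background sample B,
q_λ(i) = exp(λ·f(i))/Z(λ), Z(λ) = Σ_{j∈B} exp(λ·f(j)), fitted by
minimizing

    L(λ) = −mean_{p∈P} λ·f(p) + log Z(λ) + Σ_j β_j |λ_j|,

a convex objective solved by L-BFGS-B on the split λ = λ⁺ − λ⁻ with
non-negativity bounds (the optimizer is restarted from its own solution
up to twice; resetting the Hessian approximation reliably escapes the
flat-progress stalls L-BFGS-B exhibits near the L1 kinks — restarts from
random initial points then agree in objective to ~1e−9).

Feature classes are deliberately minimal: linear + quadratic terms per
continuous covariate (min–max rescaled to [0,1] on the background, values
clamped at prediction time) and one indicator per observed soil class.
Quadratics express the monotone and unimodal responses this analysis
needs; hinge/product/threshold features are omitted as out of scope. An
unseen soil class at prediction time gets all-zero indicators (baseline)
with a warning.

Per-feature penalties follow the standard Maxent convention
β_j = β·s_j/√m, with s_j the feature's background standard deviation and
m the presence count, so the single knob β (default 1.0) is dimensionless
and sample-size aware. A flat penalty β·Σ|λ_j| at β = 1 was rejected: on
[0,1]-rescaled features the subgradient condition |∂NLL/∂λ_j| ≤ β is then
satisfied at λ = 0 for every feature (feature-mean differences are
bounded by 1), so the fitted model would always be uniform.

Defaults: background 10,000 cells (or all valid cells if fewer), k = 10
cross-validation folds with presences-only folding, 10 runs for variable
importance. Output flavors:

* **raw** — q_λ, summing to 1 over the background (checked to 1e−8);
* **cumulative** — for each cell, the total raw probability of background
  cells at or below its raw value (ties inclusive, so a uniform surface is
  cumulative 1 everywhere); monotone in raw, on [0,1], used for
  thresholding;
* **logistic** — e^H·r/(1+e^H·r) with H the entropy of q_λ over the
  background; a cell of entropy-typical raw value maps to 0.5 (default
  prevalence 0.5), read as probability of occurrence.

Variable importance is permutation-based: per run, hold out 20% of
presences, fit on the rest, permute one variable's values across the
evaluation rows (held-out presences + background jointly), record the
held-out AUC drop; clip at zero, average over runs, renormalize to sum
to 1. Permutation importance was chosen over path-based "percent
contribution" because the latter depends on a specific training
trajectory; permutation importance is defined for any fitted model and
reproducible. AUC is the rank statistic (Mann–Whitney U normalized, ties
counted half).

## Index of shared suitability

Three formulas ship, all symmetric, [0,1]×[0,1] → [0,1], and satisfying
ISS(1,1) = 1, ISS(x,0) = 0, ISS(0,0) = 0:

| name | formula |
|---|---|
| `min_minus_gap` (default) | max(0, min(s₁,s₂) − |s₁−s₂|) |
| `harmonic` | 2s₁s₂/(s₁+s₂) |
| `product` | s₁s₂(1 − |s₁−s₂|) |

The default additionally satisfies ISS(s,s) = s (equal-suitability
monotonicity) and is computed on logistic-flavor surfaces, whose values
are interpretable as occurrence probabilities. The formula is selectable
by name so an alternative definition can be dropped in; a shared property
suite in the tests runs against every entry in the registry.

## Dutilleul's corrected correlation test

For two spatially autocorrelated variables sampled at n locations, the
Pearson correlation is computed as usual but tested with an effective
sample size

    n_eff = 1 + tr(BΣ̂ₓ) tr(BΣ̂ᵧ) / tr(BΣ̂ₓBΣ̂ᵧ),    B = I − 11ᵀ/n,

df_adj = n_eff − 2, F_adj = r²·df_adj/(1−r²) referred to F(1, df_adj).
For white noise Σ̂ = I and n_eff = n, recovering the ordinary test.

The spatial correlation matrices Σ̂ are estimated piecewise-constant over
distance classes: each off-diagonal entry receives the Moran's I of its
class, the diagonal is 1. Class resolution matters: classes must be
narrow relative to the autocorrelation range or short-range correlation
is averaged away and the test becomes anticonservative. The default is
therefore adaptive — n/2 equal-frequency classes, clipped to [10, 100] —
rather than the 10 classes the plain correlogram uses for description.
The traces are computed from double-centered matrices in O(n²) without
any matrix product, so n = 2000 samples are routine.

The package's correctness claim for this module is calibration, asserted
in the acceptance suite: on 1000 independent pairs of autocorrelated
fields (n = 200, range 10 cells) the empirical type-I error at nominal
0.05 must lie in [0.03, 0.07] while the naive test exceeds 0.15.

## Moran eigenvector maps

Connectivity is binary within a truncation distance (default: the longest
minimum-spanning-tree edge, the smallest radius keeping the graph
connected). The doubly centered connectivity BAB is eigendecomposed;
eigenvectors with positive eigenvalues — the positively autocorrelated
patterns — are returned in non-increasing eigenvalue order, orthonormal
and orthogonal to the constant. Forward selection greedily adds the
eigenvector that most reduces |Moran's I| of the regression residuals,
stopping when residual autocorrelation is no longer significant
(permutation test, α = 0.05, 199 permutations) or a cap is reached. The
selection rule is a documented choice; any subset of the basis can be
supplied to the regression directly.

## Regressions

Population and GDP responses are transformed as y = log10(x+1), which
keeps zero-valued cells in the analysis (they are retained by default;
exclusion can bias spatial samples). The breakpoint model

    y = a + b·min(x, c) + d·max(x − c, 0) + ε

is continuous at the knot, i.e. four mean parameters. Given c the fit is
ordinary least squares, so c is found by exhaustive grid search over the
predictor's [5th, 95th] percentile range at resolution 0.005, ties
resolved to the smallest candidate; candidates with fewer than three
points strictly on either side are skipped. Grid search is deterministic
and exact to the grid step, at the cost that â absorbs knot quantization
of order |b|·Δc.

AIC uses the profile Gaussian likelihood with the error variance counted
as a parameter: k = 3 (linear) and k = 5 (breakpoint), so the nested
models are directly comparable; the breakpoint r² can never fall below
the linear r². Logistic regression is maximum likelihood via statsmodels
(IRLS); perfect separation falls back to a bounded IRLS path and flags
the result instead of raising. Model chi-square is 2(LL_model − LL_null);
classification accuracy is evaluated at probability 0.5.

Prediction surfaces re-exponentiate the fitted mean (10^ŷ − 1, floored at
0) and residual maps are observed − predicted on the natural scale, whose
right-skew is a property of back-transforming a log-scale model, not a
bias (the log-scale residuals are centered).

## Synthetic data generator

The generator produces data with exactly the structure the analysis
assumes, so every estimator can be tested for parameter recovery:

* **Continuous fields** — white noise convolved with a Gaussian kernel of
  standard deviation range/2 on a padded array (no wrap-around), then
  standardized; the field's correlation function is exp(−(d/range)²),
  falling to 1/e at distance `range` (in cells). range = 0 gives
  independent cells. Defaults: two fields ("temperature", "precipitation"),
  range 8 cells on a 100×100 landscape.
* **Soil** — quantiles of an auxiliary random field (range 12), yielding
  spatially coherent patches rather than i.i.d. codes; 4 classes by
  default.
* **True niche** — logistic(linear predictor) on standardized covariates
  with linear + quadratic terms and per-class soil offsets. The canonical
  `strong_niche()` used in recovery experiments concentrates suitability
  (background mean ≈ 0.15), the regime where presence-only modelling is
  informative.
* **Presences** — cells drawn without replacement with probability ∝
  suitability, placed at cell centers. Default counts in the pipeline span
  47–290 per landuse type, matching the scale of compiled georeferenced
  record sets for such traits.
* **Population** — the two-segment relation on the log10(x+1) scale with
  Gaussian noise, back-transformed and floored at 0. Defaults
  (a, b, c, d, σ) = (0.2, 6.0, 0.3, 0.5, 0.4): a steep suitability–
  population link below the knot at 0.3 and a weak one above it.
* **Conflicts** — uniformly sampled localities labeled conflict with
  probability logistic(α + β·ISS); defaults α = −2.5, β = 5, n = 500.

What the generator does **not** emulate: real climate covariance
structure, coastlines/irregular masks, anisotropy, non-Gaussian noise,
and cultural/historical contingency. Passing recovery tests therefore
demonstrates the estimators are correct under the model's own
assumptions — not that the assumptions hold for any particular real
dataset.

## Pipeline and problem sizes

The orchestrated study derives every stage's seed by hashing the master
seed with the stage name, so adding a stage never perturbs earlier
stages' random streams, and a fixed master seed reproduces the report
bit-for-bit. Default study size is a 100×100 landscape with a 10,000-cell
background, a 2000-cell regression sample and 500 conflict localities —
sizes chosen so the full study completes in seconds on a single core
while keeping every statistical stage in its intended operating regime
(the regression sample and conflict-locality counts are the analysis
design's own values). Recovery experiments in the tests use a 200×200
landscape with 200 presences.

In the full pipeline the population surface is generated from the *true*
suitability but regressed on the *fitted* logistic suitability, as a real
analysis must; the estimated knot then lands on the fitted-suitability
scale (a monotone distortion of the truth), so it is not expected to
equal the generator's c — the direct recovery experiment, which regresses
on the same scale the data were generated from, is the parameter-recovery
check.

## Known limitations

* The Maxent variant is deliberately small: no hinge features, no
  clamping diagnostics, no jackknife importance; strongly multimodal
  responses beyond quadratic shape will be underfitted.
* The Dutilleul covariance estimate is piecewise-constant and isotropic;
  strongly anisotropic fields will be corrected only approximately.
* Breakpoint inference is conditional on the estimated knot; the reported
  slope-contrast t-statistic ignores knot-selection uncertainty.
* Eigenvector forward selection tests residual Moran's I only on the
  basis' own connectivity; other weight definitions may judge residual
  structure differently.
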