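# landuse-enm

A climate-and-soil "null model" of human landuse, built as a reusable,
tested Python pipeline. The question it operationalises: if people chose
among the basic landuse strategies — agriculture, sedentary animal
husbandry, nomadic pastoralism, hunting-and-gathering — purely on the
suitability of local climate and soil, with no history or culture in the
way, what spatial patterns of landuse, population density, wealth and
landuse conflict would we expect, and where does reality deviate?

The package is aimed at spatial ecologists and quantitative geographers
who want the full analysis chain — presence-only niche modelling, overlap
statistics, and spatially corrected regression — as composable library
functions with a synthetic-landscape generator that provides known ground
truth for every estimator.

## What's inside

**Maximum-entropy niche model** (`landuse_enm.niche`). Presence-only
suitability estimation as a Gibbs distribution over background cells:

    q_λ(i) = exp(λ·f(i)) / Z(λ),

with λ minimizing the L1-regularized negative mean log-likelihood of the
presence cells. Features are linear + quadratic terms of the continuous
covariates (rescaled to [0,1]) and indicators for soil classes. Outputs
come in three flavors: *raw* (probabilities summing to 1 over background),
*cumulative* (rank-like [0,1] score used for presence/absence
thresholding) and *logistic* (e^H·r/(1+e^H·r), read as probability of
occurrence, i.e. "suitability"). Evaluation: k-fold cross-validated AUC,
permutation variable importance, partial response curves.

**Index of shared suitability** (`landuse_enm.overlap`). For two landuse
types with suitabilities s₁, s₂, the default formula

    ISS = max(0, min(s₁, s₂) − |s₁ − s₂|)

is ≈1 only where both are well suited, and ≈0 where one clearly dominates
or both are poor — a map of potential conflict zones between landuse
traditions. Alternative formulas are selectable by name. Deviation maps
cross-tabulate a thresholded prediction against a reference
classification.

**Spatial statistics** (`landuse_enm.spatial`). Moran's I, distance-class
correlograms, Dutilleul's modified test of correlation between two
autocorrelated variables (effective sample size from the trace formula
n_eff = 1 + tr(BΣ̂ₓ)tr(BΣ̂ᵧ)/tr(BΣ̂ₓBΣ̂ᵧ), giving adjusted degrees of
freedom df_adj = n_eff − 2), and Moran eigenvector maps (MEM) with
forward selection for spatial filtering in regression.

**Regression** (`landuse_enm.regress`). Population and wealth are
analysed on the log10(x+1) scale. The breakpoint (segmented) model
y = a + b·min(x,c) + d·max(x−c,0) — continuous at the knot, four mean
parameters — is fitted by exhaustive grid search over c, compared to the
nested linear model by Gaussian AIC, extrapolated back to people/km² and
mapped as residuals. Logistic regression with Wald tests handles the
conflict analysis.

**Synthetic data** (`landuse_enm.synthetic`) generates all study inputs
with known truth: Gaussian random fields with a controlled autocorrelation
range, quantile-sliced soil patches, presences sampled ∝ suitability,
population from the breakpoint relation plus log-scale noise, and conflict
points with logistic dependence on ISS.

**Pipeline** (`landuse_enm.pipeline`) runs the whole study from one
config (YAML or `StudyConfig`) with a master seed hashed into independent
per-stage seeds; `landuse-enm run --config study.yaml` does the same from
a shell.

## Worked example

`examples/04_population_breakpoint.py` generates population from the
two-segment relation (true knot c = 0.3, slopes 6.0 below / 0.5 above,
noise σ = 0.4 on the log scale) on a 100×100 landscape, samples 2000
random cells, and re-estimates everything:

```
linear:     r2=0.716  AIC=2182.5
breakpoint: r2=0.812  AIC=1359.0  knot c=0.305 (true 0.3), slopes b=5.50 below / d=0.59 above
Dutilleul-corrected correlation: r=0.846, F_adj=457.9, df_adj=181.6 (n-2=1998), p=1.6e-51
```

The breakpoint fit recovers the knot to the grid resolution and beats the
linear model by ΔAIC ≈ 823; the Dutilleul correction discounts the 2000
spatially dependent samples to ≈184 effective observations, and the
relationship remains overwhelmingly significant. The other scripts in
`examples/` walk through the niche model (AUC 0.853, Spearman 0.916
against the generating truth), ISS and deviation maps, the conflict
logistic model with MEM filtering, and the full orchestrated study.

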