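# Methods

`sdmcascade` implements a *cascade ensemble* analysis of climate-driven
habitat suitability: an ensemble of species distribution models (SDMs) is
calibrated on presence/absence data, combined into a skill-weighted
consensus, and re-applied to an ensemble of perturbed future climates; the
agreement among the resulting binary projections is expressed in IPCC AR5
calibrated likelihood language, and aggregated changes in distribution and
diversity are tested with chi-square statistics. Everything runs on fully
synthetic landscapes whose ground truth is known, which is what makes the
package testable end to end.

## Synthetic landscape

The generator fabricates the inputs a real study would assemble from
observational rasters.

**Topography.** Smoothed Gaussian white noise rescaled to `[0, relief]`
meters (default relief 2,500 m) on a fine grid with 8×8 fine cells per
0.25° working cell, so per-cell altitude/slope statistics are nontrivial.
Every generator is a pure function of its parameters and a seed.

**Monthly climate.** Twelve monthly normals of mean/min/max temperature
(°C) and precipitation (mm/month). Temperature combines:

- a lapse-rate term, default 6.5 °C/km of block-mean elevation;
- a meridional gradient, default 0.6 °C per degree of latitude;
- a sinusoidal seasonal cycle peaking in July (amplitude 9 °C at the
  southern edge, growing 0.25 °C/degree northward as a continentality
  proxy);
- a diurnal range of 9 °C widening by 1.5 °C/km of elevation;
- smooth mesoscale anomaly fields: one annual (sd 1.0 °C) and twelve
  monthly ones (sd 0.5 °C, centered over the year so the annual mean stays
  analytic).

The anomalies represent the part of observed climate normals that
elevation and latitude do not explain (coastal influence, radiation,
exposure). They matter structurally: without them the annual mean
temperature is an *exact* linear function of mean altitude and latitude
and several bioclim surfaces differ from it only by constants, so
questions like "which single predictor drives this species?" would be
unanswerable by construction. All anomaly scales are parameters and can be
set to zero, which restores the fully deterministic surfaces used by the
analytic unit tests. Precipitation multiplies a seasonal cycle (peak in
November), an orographic enhancement (+50 %/km) and a smooth log-normal
wetness field; it is clipped at zero.

**Virtual species.** Occurrence probability is a logistic function of a
weighted sum of Gaussian-bell responses to named predictors plus optional
logit noise. The intercept is calibrated by quantile matching so that the
share of cells strictly above the presence threshold (default 2 %) equals
the requested prevalence. The noise-free suitability surface is returned
alongside the sampled one and is the ground truth for recovery tests.

**Futures.** A pseudo-GCM × pseudo-RCP × horizon grid of perturbations:
uniform temperature offsets (optionally with a spatial gradient) and
multiplicative precipitation factors. Pseudo-GCMs span a warmest/wettest
to coldest/driest gradient, mirroring how real CMIP5 ensembles bracket the
outlook. Default scenario offsets: +1.4/+1.8 °C (moderate scenario, 2050s/
2070s) and +2.0/+3.7 °C (high scenario), with a ±0.5 °C model spread and
precipitation factors 0.85–1.15.

**Regions.** Contiguous pseudo biogeographical regions as nearest-center
(Voronoi) cells of k random seeds in index space.

What the generator does *not* emulate: real geography and coastlines,
autocorrelated species ranges beyond what the environmental response
induces, dispersal limitation, land use, observation error in the presence
fractions, and GCM physics. Passing tests therefore demonstrate that the
*pipeline machinery* behaves correctly under known truth, not that any
real-world projection is accurate.

## Predictors

The 19 bioclimatic variables follow the WorldClim/ANUCLIM conventions:
quarters are 3 consecutive calendar months with December–January wrap,
ties broken by the earliest start month. Temperature seasonality (Bio4) is
100 × the population SD of monthly means; precipitation seasonality
(Bio15) is the population CV in percent, flagged NaN where mean monthly
precipitation is zero; isothermality (Bio3) is flagged NaN where the
annual range vanishes. Temperatures are floats in °C internally; the
legacy integer °C×10 convention is an output option.

Topographic predictors are computed at fine resolution and aggregated:
max/mean/min altitude and slope per working cell, plus the modal aspect
class (8 compass octants numbered 1–8, 9 = flat, 10 = undefined; ties take
the lowest class), easting in degrees east of the western cell center, and
cell-center latitude. Slope uses central differences on the fine grid with
the east–west spacing shrunk by cos(mid-latitude).

Collinearity diagnostics: pairwise Pearson r and VIF_j = 1/(1 − R²_j) from
an OLS regression of each predictor on the others. Constant predictors are
flagged undefined, never silently dropped; exact dependences give VIF = ∞.
Two correlation structures (e.g. historical vs. a future scenario) are
compared with a Wilcoxon signed-rank test on the paired upper-triangle
correlations (exact null distribution at small n via scipy).

## Occurrence and calibration splits

Fractional presence becomes binary occurrence through a *strict* threshold
(presence iff fraction > 2 %), so a cell exactly at the threshold is an
absence. Calibration/validation splits (default 70/30, 10 runs) are
stratified per class with per-class rounding; stratification guarantees
both classes on both sides whenever each has ≥ 2 cells. The paper-style
"random subset" is unstratified; stratification is a deliberate guard
against degenerate all-absence validation sets on rare species.

## Base learners

Eight algorithms behind one fit/predict contract, all scoring every cell
in [0, 1]:

| id | implementation |
|----|----------------|
| glm | logistic regression with forward stepwise term selection by AIC (max 8 terms, tiny ridge for separable data) |
| gbm | gradient-boosted trees (scikit-learn defaults) |
| cta | classification tree (min leaf 5) |
| ann | one-hidden-layer perceptron (16 units, 300 iterations) |
| sre | bespoke surface range envelope (below) |
| mars | additive piecewise-linear (hinge-basis) L1 logistic model |
| rf | random forest (100 trees) |
| maxent | L2 logistic model on linear + squared features |

The GLM's stepwise selection is the classical default for distribution-model
GLMs and is what lets permutation importance concentrate on the genuinely
informative predictor among collinear alternatives; deviance comparison
distinguishes near-duplicates that margin-based selection cannot. The
"mars" learner is an additive spline classifier in the MARS family (paired
hinges at the 1/3 and 2/3 calibration quantiles per predictor, L1
selection); "maxent" is the penalized presence/background logistic
contrast. Features are standardized on calibration statistics. Seeds fan
out deterministically per (algorithm, run) from one master seed.

**SRE.** The envelope is the [q, 1−q] per-predictor quantile box of the
calibration presences; a cell scores 1 iff every predictor lies inside its
bounds (inclusive). The default is q = 0 (the classic min/max envelope).
A nonzero q trims each of the 28 dimensions independently, so the
sensitivity ceiling decays like (1−2q)^k in the number of effectively
independent predictors — at q = 0.025 with ~10 effective dimensions
roughly half of all true presences fall outside the envelope, which is
incompatible with this package's requirement that every learner clear a
0.9 validation AUC on noise-free species. q stays configurable for users
who want the trimmed variant.

## Evaluation

All threshold metrics derive from the confusion matrix with
predicted-present iff score ≥ threshold (presence on the boundary):
sensitivity, specificity, positive/negative predictive value, overall
accuracy, TSS = sens + spec − 1, Cohen's kappa, and MCC. Undefined
denominators yield NaN, never silent zeros. AUC is the rank-based
Mann–Whitney statistic with ties counted half. The binarization threshold
maximizes sens + spec (the Youden point, i.e. the ROC-plot optimum;
kappa-maximization is available) over midpoints of sorted unique scores.

Runs join the ensemble only if validation AUC ≥ 0.85 (0.90 for designated
heterogeneous categories) *and* validation TSS ≥ 0.75, both inclusive. An
empty passing set is a valid, reported outcome.

Permutation importance: shuffle one predictor across cells, re-predict,
and score (1 − Pearson r between standard and shuffled predictions) × 100,
averaged over permutations (default 3). Per-run importances are optionally
standardized to sum to 100 before cross-run averaging.

## Cascade ensemble

Consensus weights are proportional to skill above chance (AUC − 0.5,
floored at zero) and normalized to sum to one, so a chance-level run
contributes nothing. The consensus score is the weighted mean of run
scores, binarized at the ROC-optimal threshold against the observed
occurrence over all valid cells. Projection holds the nine topographic
predictors fixed and swaps in the 19 future bioclim surfaces.

Member agreement per cell maps to the likelihood scale 0 → not suitable,
1 → extremely unlikely, 2–3 → unlikely, 4–6 → about as likely as not,
7–8 → likely, 9–10 → extremely likely (counts of 10 members). For other
member counts the bin edges scale proportionally (ceiling of the
reference-edge fraction), preserving a gap-free partition. Sub-ensembles
(sub-CEMs) average the member binaries across climate models per
(scenario, horizon) and binarize at a fraction of 0.5 (model majority).

## Change analysis

Regional distribution: pixel counts of presence per category per state
(historical and each sub-CEM), optionally per region. Local diversity: the
histogram of per-pixel category richness, with the most frequent nonzero
richness flagged (smallest value on ties). The conservation identity
Σ r·count(r) = Σ category presence counts holds by construction and is
asserted in tests.

State pairs are compared with the chi-square homogeneity test on the 2 × k
contingency table, no continuity correction (counts here are large);
adjacent bins are pooled until every expected count reaches 5, and the
test requires ≥ 2 usable bins with expected counts ≥ 1. Default alpha is
0.001. No multiple-testing correction is applied across pairwise
comparisons by default (a Holm option exists). The compact letter display
assigns one letter per maximal clique of the "not significantly different"
graph, ordered deterministically by smallest state index.

## Pipeline, problem sizes and reproducibility

`run_pipeline` executes simulate → predictors → occurrence → calibrate →
evaluate → ensemble → project → cascade → change from one config, with
per-stage seeds derived from the master seed and a manifest listing every
artifact with its producing stage. Rasters are written as ESRI ASCII
grids, tables as CSV, the config as YAML. Species with no passing runs
are dropped from the cascade with a logged notice; a config without
future scenarios stops after the historical ensemble.

Two bundled configurations define the package's own study conditions: a
two-species demo on a 30 × 30 grid (3 algorithms, 2 pseudo-GCMs × 2
scenarios) that runs in seconds, and a reference configuration with ten
virtual forest categories on a 64 × 68 grid (4,352 cells), eight
algorithms, ten calibration runs and a 5-model × 2-scenario × 2-horizon
cascade. Reference niches are anchored to quantiles of the realized
predictor fields — the standard virtual-species construction — so every
category occupies a recoverable niche inside the sampled gradient
regardless of the landscape seed, with logit noise (sd 0.25–0.3) low
enough that each category retains admissible runs under the dual filter.
Recovery experiments use 36 × 36 grids with noise-free single-predictor
species over five seeds.

## Known limitations

- The likelihood vocabulary communicates ensemble agreement, not
  probability of occurrence; it inherits every bias of the member models.
- SRE scores are binary, so its AUC is (sens + spec)/2 and it cannot rank
  cells within the envelope.
- The MaxEnt-style learner is a penalized logistic stand-in, not the full
  MaxEnt feature machinery (product/threshold/hinge features, background
  weighting).
- The chi-square tests treat pixels as independent observations; spatial
  autocorrelation makes them anti-conservative on real rasters.
- Virtual species respond additively on the logit scale with no
  interactions or dispersal constraints; recovery results bound what the
  machinery can do under ideal truth, not field performance.
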