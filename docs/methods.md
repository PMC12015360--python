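# Methods

## The problem and the model

Cluster household surveys record individuals at geocoded primary sampling
units. For a chosen data-quality attribute (a heaped age, a missing birth
date, an implausible height-for-age z-score) each cluster *s<sub>i</sub>*
yields a count *y(s<sub>i</sub>)* out of *m(s<sub>i</sub>)* eligible records.
The model is a binomial spatial generalized linear mixed model:

- *Y(s<sub>i</sub>) | m(s<sub>i</sub>) ~ Binomial(m(s<sub>i</sub>), p(s<sub>i</sub>))*
- *logit p(s<sub>i</sub>) = x(s<sub>i</sub>)ᵀβ + ω(s<sub>i</sub>) + ε(s<sub>i</sub>)*

where *x* are log-transformed, standardized covariates, *ε* is an iid
Gaussian nugget with variance σ²<sub>ε</sub> (cluster-level, non-spatial
noise — interviewer effects, survey-team effects), and *ω* is a zero-mean
stationary Gaussian process with Matérn covariance

σ² · (2<sup>ν−1</sup>Γ(ν))<sup>−1</sup> (κd)<sup>ν</sup> K<sub>ν</sub>(κd),

ν fixed at 1 (it is not identifiable from data of this kind), κ = √(8ν)/r.
The range *r* is the distance at which the correlation has decayed to
√8·K₁(√8) ≈ 0.1397 — computed, not assumed; the test-suite pins it to
[0.13, 0.15]. Distances are Euclidean km on planar synthetic regions and
great-circle (haversine, radius 6371 km) for lon/lat data.

### Priors

- β ~ N(0, 10³I), effectively non-informative.
- σ<sub>ε</sub> and σ carry penalized-complexity (exponential) priors
  calibrated by tail statements P(σ<sub>ε</sub> > 3) = 0.01 and
  P(σ > 3) = 0.01, i.e. rate λ = −ln(α)/U. On the logit scale a standard
  deviation of 3 is already an extreme amount of heterogeneity, so these
  shrink gently toward the non-spatial base model.
- The range carries the 2-D PC range prior with
  P(r < r₀) = 0.01, density λ r<sup>−2</sup> exp(−λ/r), λ = −ln(α)·r₀.
  "Region size" for r₀ is operationalized as 5% of the maximum pairwise
  distance among the data locations (the choice is exposed via
  `PriorSpec.range_r0`).
  Both calibrations are verified by Monte Carlo in the tests (tail masses
  within 3 SE at 10⁵ draws).

### Inference

No sparse finite-element mesh approximation of the Matérn field is used: at the few-hundred-cluster
scale this package targets, the Matérn covariance is evaluated exactly and
densely over the cluster locations. This is the package's one deliberate
methodological simplification relative to large-scale continental practice,
where a finite-element approximation of the same Matérn field is the norm;
at desk scale the exact covariance is both faster and free of mesh-design
choices.

Inference runs on the collapsed latent vector u = ω + ε (covariance
Σ<sub>ω</sub> + σ²<sub>ε</sub>I), which avoids a singular decomposition when
clusters share a grid cell:

1. For fixed hyperparameters θ = (log σ, log r, log σ<sub>ε</sub>), the joint
   mode of (β, u) is found by damped Newton iterations, and the Laplace
   approximation gives a Gaussian approximation to the conditional posterior
   and an approximate marginal likelihood.
2. An adaptive random-walk Metropolis chain (target acceptance 0.3, scale
   adapted during burn-in) samples θ from the Laplace-approximated marginal
   posterior; each proposal re-optimizes the latent mode warm-started from
   the current one.
3. Posterior draws (1000 by default) resample θ states from the chain and
   draw (β, u) from the Gaussian approximation at each state.

When every hyperparameter is held fixed and the latent dimension is small
(≤ 16), an exact adaptive-Metropolis sampler over (β, u) replaces steps 1–3;
its agreement with a dense Gauss-Hermite quadrature oracle (posterior mean of
p within 0.01, posterior sd within 10%) is the correctness contract for the
likelihood and covariance code, checked on committed ≤ 4-cluster fixtures.
The Laplace path is validated frequentistly: over repeated simulated surveys
(300 clusters) the 95% credible intervals for β cover the truth at the
nominal rate within binomial tolerance.

### Prediction

Posterior surfaces condition ω at the prediction cells on u directly
(cov(ω<sub>grid</sub>, u) = Matérn cross-covariance; one-step Gaussian
conditioning), then apply the inverse logit to x'β + ω per draw. The iid
nugget is **excluded** from predicted surfaces by default — it is read as
survey-process noise, not a property of place — and can be added back with
`include_nugget=True`; predicting at the data locations with the nugget
added back reproduces the fitted probabilities within a paired tolerance of
0.02 on simulations. District standard deviations therefore also come in two
variants, with and without nugget, via the same toggle.

## Indicators

- Age heaping: m = persons aged 23–62 inclusive, y = ages divisible by 5.
  The 40-age window contains 8 such ages, hence the exact 20% natural
  baseline.
- Incomplete age: m = women 15–49 inclusive, y = birth month OR year missing.
  The woman's own birth date is used throughout.
- Flagged HAZ: m = all anthropometry-eligible children listed (so missing
  heights count in numerator and denominator, making "missing" interpretable
  as a share), y = HAZ missing or strictly outside [−6, +6]; boundary values
  are plausible. The window is the standard WHO plausibility limit for
  height-for-age.
- Clusters with m = 0 are kept with an `excluded` flag and skipped by the
  model, never silently dropped.

## Synthetic data

The generator is first-class code, not a fixture: it produces regions whose
statistical structure is exactly the model above, so parameter recovery and
round-trip identities are meaningful.

- **Region**: a rows × cols grid of square cells (5 km default). Population
  and covariates are log-normal — the exponential of smooth Gaussian fields —
  mirroring the heavy right skew of real population, nightlight and malaria
  layers. Districts are a seeded k-means partition of cell centroids
  (compact, contiguous-ish polygons built as unions of cell squares).
- **Clusters**: cells drawn with probability proportional to population;
  cluster sizes m ~ 1 + Poisson(mean − 1) so every cluster has at least one
  record (survey programs do not publish a size model; the Poisson choice is
  this package's, with an exact-count mode for round-trip tests). Default
  mean cluster size 25, a typical order for per-cluster eligible respondents.
- **Counts**: y ~ Binomial(m, p) with logit p = x'β + ω + ε from a fresh
  Matérn draw and nugget. Defaults — 300 clusters, β = (0.5, −0.3), σ² = 1,
  r = 60 km, σ²<sub>ε</sub> = 0.1, 30 × 30 grid — are the simulation
  conditions used by the recovery and validation tests.
- **Records**: in exact-count mode each cluster emits exactly y error-bearing
  rows out of m, so indicator computation inverts the generator exactly. In
  stochastic mode the age-heaping generator uses the inversion
  h = (W − 0.2)/0.8 for the per-record heaping probability, so the
  terminal-digit-0/5 share equals the target W in expectation on top of the
  natural 20% baseline of uniformly distributed terminal digits. This
  inversion is a construction of this package (targets below 20% are
  unreachable and raise). The other two indicators carry the error with
  probability W directly.
- **Nightlights**: integer digital numbers in [0, 63]; town centres (placed
  preferentially in populated cells) peak at DN 40–63 and decay
  exponentially with distance, giving a DN ≥ 15 "lit settlement" set and
  hence a distance-to-settlement gradient.

What the generator does **not** emulate: realistic settlement morphology,
GPS displacement of cluster coordinates (a jitter utility exists for
sensitivity experiments but is off by default), conflict-driven missingness,
multi-survey temporal structure, and real covariate maps. Passing tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not the fidelity of any real-world map.

## Validation

10-fold cross-validation with seeded random splits of the cluster locations.
Observed values are raw per-cluster proportions y/m; predictions are
posterior means at held-out locations (nugget excluded). Metrics per fold,
then averaged across folds: %Bias = 100·Σ(p̂−p)/Σp,
RMSE = √(mean((p̂−p)²)), MAE = mean(|p̂−p|), and the Pearson correlation.
RMSE is the standard root-mean-square prediction error on the probability
scale. A fold whose observed sum is zero has undefined %Bias and is flagged
rather than imputed; perfect predictions report correlation 1 when both
vectors vary and NaN (undefined) when degenerate.

## Remoteness analysis

Distance from each cluster to the centroid of the nearest raster pixel with
DN ≥ threshold (15 by default; 10 and 20 are available, and a binary
settlement raster with threshold 1 subsumes non-luminosity settlement data).
The regression is a maximum-likelihood binomial logistic model of (y, m) on
g(distance) with one fixed-effect intercept per country (statsmodels GLM
underneath). The default transform is g(d) = log10(d + 1 km); identity and
natural log are config options, since distance-response curves of this kind
are conventionally displayed on a log scale and the regressor choice is
free. This module consumes only raw indicator counts, never modelled
surfaces, so the estimated gradient cannot be an artifact of regressing a
model's output on its own covariate. Prediction curves can hold the fixed
effect at a reference country or average over countries; both are exposed
because the choice changes the display, not the slope.

## Aggregation

District value per posterior draw = Σ pop<sub>c</sub>·p<sub>c</sub> / Σ
pop<sub>c</sub> over member cells; mean and sd are then taken across draws,
reported in percent. Cell membership follows the cell-centroid containment
rule with ties to the lowest district id. National aggregation of district
values with district population weights reproduces direct cell-level
aggregation to 1e−10 (a convexity/conservation identity asserted in tests).
An optional mask flags cells below 10 persons per 1 × 1 km for map display
only; it never enters the arithmetic.

Pseudo-locations for clusters without GPS coordinates: 1000 candidate points
per latent location sampled within the admin unit proportional to cell
population (uniform within a cell), pooled, then clustered by seeded k-means
with k = the number of latent locations; the centroids are the
pseudo-locations and carry the unit-level average indicator value. A
centroid landing outside a non-convex unit is snapped to the nearest
candidate. Pooling the candidate clouds and setting k to the latent count is
this package's reading of the procedure; it is stated here because other
readings (per-location clustering) exist.

## Exploratory tools

- Empirical logit y* = log((y+0.5)/(m−y+0.5)), finite at both boundaries.
- Covariates: log then z-score; columns containing zeros (nightlights,
  malaria) receive an offset of half the smallest positive value before the
  log — an offset rule chosen here, documented as such. Transform parameters
  are frozen for reuse on the prediction grid.
- VIF per covariate from the R² of an OLS regression (with intercept) on the
  remaining covariates; values ≥ 4.0 are flagged, exact dependence reports
  `inf` rather than crashing.
- Empirical variograms use the classical Matheron estimator with 15
  equal-width bins to half the maximum pairwise distance by default.
- Moran's I uses row-standardized weights (queen contiguity when built from
  polygons) and a seeded permutation test with 999 permutations; the
  permutation-null mean −1/(n−1) is a test invariant. The weight matrix
  convention matters for comparability across implementations, so it is part
  of the JSON report.

## Numerical choices and limitations

- A jitter of 10⁻¹⁰·max(σ², 1) on the covariance diagonal guards Cholesky
  factorizations; prediction adds 10⁻¹⁰σ² to the conditional covariance.
- Newton optimization uses backtracking line search; MCMC proposals that
  produce non-finite Laplace objectives are rejected.
- Sampler lengths in tests and in the acceptance script are reduced
  (hyperparameter chains of 100–350 iterations, 150–500 retained draws,
  30–50 replicate surveys) — sizes at which the recovery and calibration
  checks are already stable.
- Known limitations: the Laplace step approximates the latent conditional by
  a Gaussian, which slightly underestimates skewness for clusters with very
  small m; duplicate cluster locations are supported through the collapsed
  parameterization but make their spatial effects perfectly correlated;
  dense covariance scales as O(n³) and is intended for n up to a few
  thousand clusters; the kriging imputer fits an isotropic exponential
  variogram and is meant for smooth covariates, not for the indicator
  surfaces themselves.
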