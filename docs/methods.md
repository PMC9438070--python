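# Methods

This note documents the models, the defaults and the choices made where
the design was genuinely open.  It states no empirical result beyond what
the test suite and `scripts/acceptance.py` compute.

## Dysregulation scores

Each biomarker is normalized (natural log where flagged in the default
panel; a square-root option exists but no default marker uses it, since
only log-transformed markers are identified in the source panel), then
standardized against the **first-visit reference population**: centred at
the reference mean and divided by the reference SD ("UV scaling").  Entry
visits represent a population screened for good general health, which is
what makes them a meaningful reference for later deviation.

Dysregulation is the Mahalanobis distance `D_M = sqrt(zᵀ Σ⁻¹ z)` of the
standardized profile from the reference centroid, using the reference
correlation matrix Σ.  The global score uses all 30 markers; each system
score uses only that system's markers and the corresponding sub-block of
Σ, so system scores are invariant to markers outside the system.  Platelet
count belongs to no system and enters the global score only.

Numerical choices:

- Σ is shrunk toward the identity with weight 1e-3 only when its condition
  number exceeds 1e8 (30 markers on ~1500 reference rows is stable; the
  guard exists for small synthetic references).  Singularity beyond that
  is an error, not silently patched.
- Observations missing any marker required by a score get a missing score
  (logged); nothing is imputed, matching the complete-case framing of the
  analysis models.
- Scores are log-transformed then Z-transformed (population-SD convention,
  ÷n) over the analysis sample before model fitting.  A raw score of
  exactly 0 (only reachable at the reference centroid) is floored at a
  configurable epsilon with a warning.

## Biological ages

**Phenotypic age** maps a linear predictor in 9 biomarkers plus
chronological age through a Gompertz 10-year mortality risk and back to
the age scale.  The coefficients, Gompertz shape and age-mapping constants
are shipped as a config object with units declared per input
(`PhenoAgeCoefficients`), transcribed from the published NHANES-IV
calibration rather than hard-coded in the computation; the test oracle
evaluates the formula chain independently instead of trusting any
constant.  C-reactive protein is not assayed in the target cohort, so the
default policy substitutes one fixed CRP value (default 0.42 mg/dL,
configurable) for every individual; the computation is then invariant to
any supplied CRP.  A mortality score outside (0, 1) is treated as a unit
error and raised, because it almost always means an input arrived on the
wrong scale.

**Klemera–Doubal age** regresses each candidate marker on chronological
age over the reference sample, keeps markers with |Pearson r| ≥ 0.1
(configurable; a missingness-based exclusion list is applied first), and
combines them as

    BA = [Σⱼ (xⱼ − qⱼ)·kⱼ/sⱼ²  +  CA/s_BA²] / [Σⱼ (kⱼ/sⱼ)²  +  1/s_BA²]

The age-corrected variant is the default.  `s_BA²` can be fixed or
estimated from the calibration sample as the variance of the uncorrected
estimate around age minus the noise-driven component implied by the
characteristic marker-age correlation (r_char² = mean squared r over
selected markers); a non-positive estimate — markers nearly exhaust age —
is floored at 1 year².  Both variants are exposed because the exact
estimation procedure differs between published implementations.  A marker
with residual SD ~0 is a deterministic function of age; its weight 1/s²
then dominates, which is the intended limiting behaviour.  Calibration
and estimation commute with unit rescaling of any marker.

## Nutrient predictors

**Relative intake.** Typical daily intake of each macronutrient (kJ/day)
is predicted by a linear regression on age, sex, weight, height and PASE
physical-activity score (a GAM-flavoured alternative was considered; the
linear form is the default because the requirement structure is nearly
linear and the fit is reused as a divisor, where stability matters).
Relative intake is `100·(observed − predicted)/predicted`: 0 means eating
the typical amount, 100 means eating twice it.  Predictions are floored
at 1% of the fitted mean before division — only reachable far outside the
training domain.

**Micronutrient reduction.** Pearson correlations of raw intakes feed
complete-linkage agglomerative clustering on the distance 1 − r; the tree
is cut at height 1 − 0.65, which with complete linkage yields exactly the
groups whose every within-cluster pairwise correlation is ≥ 0.65.
Multi-member clusters are summarized by the first principal component of
their standardized member intakes (correlation-scale PCA, because the
nutrients carry heterogeneous units), sign-oriented to correlate
non-negatively with members; everything else stays a singleton.  All 19
reduced variables are Z-scaled with stored means/SDs, and a fitted
reduction is re-applied to new data from its stored loadings, never
refitted.

## The GAM engine

The additive model is Gaussian with three building blocks:

- **Thin-plate regression splines** in 1–3 dimensions.  Inputs are
  standardized internally (scalings stored with the fit) so the penalty is
  isotropic regardless of units.  The basis is knot-based: up to k knots
  placed by k-means on the unique standardized input rows (unique rows are
  lexicographically sorted first, making knots — and hence the whole fit —
  invariant to row order).  Penalty order follows the dimension: m=2 for
  one and two dimensions, m=3 for three, so a 3-D smooth has an
  unpenalized quadratic null space of 10 functions — a fully smoothed 3-D
  term retains 9 degrees of freedom beyond the intercept, which is why
  saturated smooths report edf = 9.  Default basis dimensions: k = 10
  (1-D), 20 (2-D), 30 (3-D).  Basis columns are sum-to-zero centred for
  identifiability against the intercept.
- **Subject random intercepts** as ridge-penalized group dummies — the
  contract is shrinkage toward zero with one smoothing parameter playing
  the role of the noise-to-subject variance ratio.
- **Parametric categorical terms** (dummy-coded, first level reference).

Smoothing parameters minimize the restricted marginal likelihood
(penalties integrate out exactly for a Gaussian response); the optimizer
is Nelder–Mead over log-smoothing-parameters, clipped to [−18, 28].  The
engine was cross-checked against an independent reference GAM
implementation on shared fixtures (matching REML profiles, edf and fitted
values); that reference is used only as a test oracle.

Reported per fit: edf per term (trace of the hat-map restricted to the
term's columns), percent deviance explained, AIC (−2·logLik + 2·(edf+1)),
scale, convergence flag, and a Wald-type test per smooth term.  The test
statistic is βᵀV⁻ β on the Bayesian coefficient covariance (fully shrunk
directions contribute ≈ 0); its reference df is the
smoothing-uncertainty-corrected edf, tr(2F − FF) over the block, which
exceeds the plain edf and protects the test from anti-conservatism under
REML-estimated penalties.  Smooth-term p-values are approximate by
construction and differ across engines; the package's own guarantee is
calibration, verified by seeded null simulations in the test suite, not
numerical equality with any other implementation.

Predictions carry pointwise standard errors from the Bayesian covariance;
population-level predictions set the random intercept to zero.  The
default covariate profile for reported predictions is: numeric covariates
at the sample mean, sex = men, smoking = not current.

## Model battery and comparison

Models 1–8 share outcome = log+Z score and a subject random intercept.
Model 1: absolute macronutrient triple (kJ/day), no covariates.  Model 2:
relative-intake triple.  Models 3/4: relative triple plus confounders
(income, education years, alcohol, PASE, age as 1-D smooths; sex and
smoking parametric), model 4 adding comorbidity count.  Models 5/6: a
micronutrient triple with the same confounder sets.  Models 7/8: both the
micronutrient and the relative-macronutrient triples simultaneously — two
separate 3-D smooths, deliberately not a 6-D smooth.  The macro triple in
models 7/8 is the relative-intake one, for continuity with models 2–4.
The screen model is the micronutrient triple plus random intercept only.

AIC comparison requires identical outcomes and estimation samples; a
model is "favoured" only when its advantage exceeds 2 points, otherwise
fits are reported as equivalent.

## Combinatorial screen

All C(n,3) unordered triples of the reduced variables (969 at n=19) are
fitted per outcome with the screen model; the smooth-term p-value is
recorded.  Fit failures are data (missing p), not crashes, with an abort
threshold on the aggregate failure rate.  The run is resumable via an
append-only checkpoint keyed by (triple, outcome), and fits are
independent, so execution order cannot change results.

BH false-discovery-rate correction is applied **within outcome** across
triples by default (the pooled-across-outcomes variant is available by
config); treating the dependent p-values as independent is conservative
for discovery counts.  Tally definitions: triples significant for ≥ 1
outcome; of those, triples significant only for ageing outcomes
(phenotypic and KDM age); triples significant for every outcome outside a
stated exclusion list; and triples containing a named variable.

SD-shift predictions move one variable δ·SD above its sample mean with
all other intakes at their means and covariates at the reference profile;
in raw units the evaluation point is mean + δ·SD (e.g. a variable with
mean 4.75 and SD 2.73 shifted by +2 SD is evaluated at 10.21).

## Surfaces

Surfaces grid two axis nutrients over the 1st–99th percentiles of their
observed values (extreme dietary profiles are rare, and the SE of the
surface is the proxy for sample density, so extrapolation is avoided);
the block's third nutrient is fixed at its population median for raw
intakes and its mean for Z-scored screen variables.  Exports are CSV
(values + SEs, lossless round trip), YAML metadata (profile, fixed
values, cap, grid) and a raster with a diverging palette clipped at ±0.8
SD — a conventionally large effect; clipping is visual only and never
alters stored values.

## Synthetic cohort

The generator emulates the study conditions: 1560 subjects by default,
ages 67–84 at entry, up to 4 annual visits with 10%/visit monotone
dropout, ~48% men, heights/weights/BMI typical of community-dwelling
older adults, PASE ~ N(90, 40) truncated at 0, log-normal income with 31%
of values missing completely at random, ~8% current smokers, Poisson(3)
comorbidities, 12% diabetes and 10% prescribed-diet flags.

Macronutrient intakes are log-normal around a requirement function linear
in weight, height, age, sex and PASE (guaranteeing positivity and a
recoverable relative-intake signal), with a subject-level persistence
term.  Micronutrients follow a Gaussian copula with seven planted
clusters (sizes 4,3,3,2,2,2,2; within-cluster r = 0.8) over a global
factor (between-cluster r = 0.1), mapped to log-normal marginals with
field-realistic means — α-tocopherol at the published population mean of
4.75 mg/day — so the clustering stage recovers 7 clusters and 19 reduced
variables under defaults.  Biomarkers load on one latent factor per
physiological system (correlation 0.3 by default) with Table-style means
and SDs as baselines; log-scale markers are anchored so that a noise-free
simulation returns the configured mean exactly.  A subset of markers
carries planted age slopes (±0.03–0.06 SD/year) so biological-age
calibration has age-correlated markers to select.  Planted `EffectSpec`
entries add linear, quadratic, saddle or interaction responses in
standardized intake units to a marker or a whole system latent.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: 24-h-recall measurement error and
systematic reporting bias, day-of-week and seasonal intake structure,
supplement intake, visit-to-visit persistence of micronutrient intakes,
informative (health-related) dropout, and missingness mechanisms beyond
MCAR income.  Effects recovered from synthetic data validate the
machinery, not the epidemiology.

Dataset-construction steps mirror the real-data workflow: the
exclusive-dataset filter removes observations with diabetes, prescribed
diet, or BMI strictly outside [22, 29.9] (bounds retained), then removes
every observation of subjects whose weight CV (population SD / mean)
exceeds 0.04 over their surviving observations — subject-level removal
after row-level filtering makes the operation idempotent.  Income
imputation replaces missing values with the participant's mean observed
income; participants with no observed income stay missing.  Income is
treated as time-varying with per-visit missingness (the recording
frequency in the source cohort is ambiguous; this choice makes
participant-mean imputation behave as described).

## Problem sizes in the shipped checks

The test suite and acceptance script run at sizes chosen to make the
statistical properties sharp while staying desk-scale: Mahalanobis
distribution checks at n = 5000 × 30 markers; KDM recovery at n = 2000;
GAM null calibration at 200 seeded 1-D replicates; the screen null at the
8-variable/56-triple/2-outcome/n = 500 configuration replicated over
seeds (within one screen the 56 p-values per outcome share an outcome
draw and are strongly dependent, so rejection rates are averaged over
replicate screens and judged by their empirical spread rather than a
single-dataset binomial band); U-shape recovery at n = 1000 observations
from 250 subjects.  The full-scale screen (969 triples × 8 outcomes)
runs through the same code path via the CLI and checkpointing.

## Known limitations

- The Wald smooth-term test is approximate; very small p-values are
  order-of-magnitude statements, not exact tail probabilities.
- Knot-based thin-plate bases with k = 30 cap a 3-D smooth's resolvable
  structure; raise `k` for sharper surfaces at cubic cost in the basis.
- The REML optimizer is derivative-free; with many smooth terms (models
  7/8 carry ~9 penalty parameters including covariate smooths) it can
  terminate at a slow-to-improve plateau — the convergence flag and
  lambda values are reported for inspection.
- `s_BA²` estimation follows one published variant; cohorts with very
  weak marker-age correlation floor it, pulling KDM age toward
  chronological age (the conservative direction).
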