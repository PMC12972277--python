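# Methods

This note documents the models, numerical choices, and defaults behind the
`agegaps` package, and what the synthetic cohort generator does and does
not emulate.

## Age-gap models

### PLS regression (SIMPLS)

Both age models are univariate-response partial least squares regressions
fitted with the SIMPLS algorithm: predictors are centered and scaled to
unit sample SD, the response (age, years) is centered, and components are
extracted by deflating the cross-covariance vector s = X′y against an
orthonormal basis of the loading space. Score vectors are orthonormal by
construction (checked to 1e−8), and for a univariate response SIMPLS
coincides with NIPALS — a test asserts equality against an independent
NIPALS implementation. With as many components as the predictor rank, PLS
predictions equal OLS predictions; this full-rank equivalence is the main
correctness oracle.

Per-component explained response variance is q²ₐ/SS_y (qₐ the y-loading on
the orthonormal scores), reported per training fold and averaged. The
cognitive model uses 19 predictors and 3 components, the brain model 9
predictors and 2 components; `suggest_components` implements the elbow
rule (stop when the marginal gain drops below a threshold, default 5
percentage points) but is advisory only — component counts are pipeline
configuration.

### Cross-validation and stratification

Ten-fold, age-stratified: subjects are sorted by age (stable sort), dealt
into consecutive blocks of K = 10, and fold labels are permuted within
each block by the seeded generator, so every fold spans the age range and
fold sizes differ by at most one (346 subjects → folds of 34–35). Each
subject is predicted exactly once by a model never trained on it.

### Bias correction

Predicted age regresses toward the mean: the young are overestimated and
the old underestimated. A line ŷ = αy + β is fit by least squares on the
pooled out-of-fold predictions (per-fold fitting is available), and the
default *offset* correction adds back the age-dependent bias,
ŷc = ŷ + y − (αy + β). Two algebraic consequences serve as tests: on the
fitting sample corr(gap, age) = 0 to machine precision, and the regression
of corrected predictions on age has slope 1, intercept 0. The *rescale*
variant ŷc = (ŷ − β)/α is provided (undefined for α ≈ 0); both are exposed
because the literature uses both and neither is canonical. Gaps are
ŷc − y; negative = younger than expected. The corrected R² is structurally
higher than the raw out-of-fold R² (the correction re-injects age), which
is why both are reported.

## Eligibility screening

A subject is excluded when raw MMSE < 26, any age/sex/education-adjusted
screening z-score is below −1.5, or the actuarial Jak/Bondi criteria hold:
two tests below −1 SD within one cognitive domain, or at least one test
below −1 SD in each of three domains. The decision is monotone in the
z-scores (lowering a score can never readmit a subject) — a property
test. The screening-test → domain map is user-supplied configuration; the
generator ships a 10-test battery with a three-domain map
(memory / language / speed-executive).

## Preprocessing

* **Box-Cox**: λ maximizes the profile log-likelihood, coarse grid on
  [−5, 5] (201 points) plus bounded refinement (xatol 1e−5); agreement
  with an exhaustive 2001-point grid within 0.01 is an acceptance-level
  check. Nonpositive inputs get an automatic shift of 1 − min, recorded in
  the fitted spec.
* **Normalizing-transform selection** (for the lifestyle block): candidates
  are identity, shifted log, shifted square root, Box-Cox, and rank-based
  inverse normal (Blom offsets); the winner minimizes a Pearson χ²/df
  statistic against a fitted normal with k = ⌈2n^0.4⌉ equiprobable
  classes. Variables that a Shapiro-Wilk test already accepts as normal
  (p ≥ 0.05) are left untouched; variables that remain non-normal after
  transformation are used as-is.
* **Direction inversion** is plain negation, logged so that higher values
  mean more pathology/impairment everywhere (hippocampal volumes, gray
  matter thickness; TMT B/A ratio and the response-inhibition score on
  the cognitive side).
* **TICV adjustment**: default residual method (volume regressed on total
  intracranial volume, sample mean re-added; a constant-TICV design
  degenerates to the identity); ratio method by configuration.
* **Outlier fencing**: values strictly outside Q1 − 3·IQR / Q3 + 3·IQR,
  quartiles by linear interpolation between order statistics (numpy's
  `linear` convention), with listwise deletion. The strict inequality
  means a value exactly at the fence survives. Fencing runs after the
  transforms and before residualization.
* **Age/sex residualization**: fit value ~ age + sex; if the omnibus
  F-test has p < 0.05 keep the residuals (grand mean re-added), otherwise
  test age-only and sex-only models and residualize on any individually
  significant predictor, else leave the variable unchanged. The cascade
  resolves the ambiguity of "jointly, then individually" decision rules;
  α is configurable. Idempotent on the residualized path. Single-sex
  designs fall back to age-only with a warning.
* **Cognitive missingness**: subjects with more than 3 of 19 scores
  missing are excluded; remaining holes are filled with the subject's own
  mean z-score over observed tests.
* **Lifestyle imputation**: chained linear regression — column-mean
  initialization, then each incomplete variable is regressed on all others
  and its missing cells refilled, sweeping in a seed-determined order
  until the largest change falls below 1e−4 column-SDs (max 25 sweeps).
  Deterministic given the seed; a masked-cell benchmark requires it to
  beat column-mean imputation on factor-structured data.

## Lifestyle profiles

PCA is the eigendecomposition of the sample correlation matrix; loadings
are stored as eigenvector × √eigenvalue (variable–component correlations;
raw eigenvectors retrievable), each component sign-flipped so its
largest-magnitude loading is positive. Scores are the z-scored data
projected on the eigenvectors (in-sample), so score variances equal
eigenvalues. Display thresholding (|loading| < 0.2 blanked) never touches
the stored result. No rotation and no unique-variance factor model are
provided — profiles are unrotated PCs by design.

**Horn's parallel analysis** simulates standard-normal tables of identical
dimensions (default 5000 iterations) and retains component k while its
observed eigenvalue exceeds the rank-k reference, stopping at the first
failure. Two references are exposed: the per-rank *mean* (default, the
convention of the classical procedure) and a per-rank *centile* (default
95th). The mean reference accepts the first noise eigenvalue about half
the time by construction, so null-retention properties ("noise tables keep
≤ 1 component") are stated and tested under the centile reference; strong
7-factor structures are retained in full under either. Even under the
centile reference a pure-noise table retains ≥ 2 components in roughly 2%
of samples — an irreducible property of the sequential rule, worth knowing
before reading a retention count as evidence.

## Association and mediation

Linear models (gap ~ PC1..PCk + sex, k = retained components) are ordinary
least squares with t-based 95% CIs; collinear designs are rejected with
the aliased terms named. APOE ε4 contrasts are one-sided two-sample
t-tests with pooled variance (carriers > non-carriers) and Cohen's d on
the pooled SD. No multiple-testing correction is applied by default
(per-term interpretation at α = 0.05); a Holm adjustment can be applied
downstream.

Mediation follows the quasi-Bayesian simulation approach for linear,
no-interaction mediator/outcome models: draw both models' coefficient
vectors from multivariate normals centered at the OLS estimates with the
estimated coefficient covariance (Cholesky with a 1e−12 jitter), compute
ACME = a·b, ADE = c′ and total = ACME + ADE per draw (the identity is
exact within every draw), and summarize by the draw mean (median for the
proportion mediated, which is heavy-tailed), percentile intervals, and a
sign-based Monte-Carlo p-value 2·min(Pr > 0, Pr < 0). The treatment
contrast is control 0 → treat 1, i.e. effects are per unit of the
treatment variable; for PC scores (variance = eigenvalue) coefficients
scale accordingly, while p-values do not depend on the scaling. Default
10,000 draws; fewer than 1000 triggers a warning. As draws grow the ACME
point estimate converges to the analytic product â·b̂; at 2000 draws the
deviation is within 2 Monte-Carlo standard errors in ~95% of runs (a
statement about the estimator's own randomness, so individual runs
outside 2 SE are expected at the usual rate).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not raw modalities (no images, assay kinetics, or questionnaire items).

* **Age**: uniform on [60, 95] by default (a bimodal option thins the
  75–80 stratum); sex balanced; APOE ε4 prevalence 23%.
* **Gaps and mediation**: a latent brain age gap u = a·F₂ + e_B and
  cognitive age gap v = c′·F₂ + b·u + e_C (years), with F₂ the "active
  life" lifestyle factor. Defaults a = −0.52, b = 0.167, c′ = −0.437
  (so a·b ≈ −0.087 and total ≈ −0.524), e_B SD 3.4, e_C SD 3.9 — effect
  and noise scales chosen to match the magnitudes such cohort analyses
  report.
* **Cognitive scores** load on standardized cognitive age (age + v) with
  target correlations spread over 0.19–0.46 in magnitude (impairment
  direction), plus a common cognitive factor (30% of non-age variance)
  and idiosyncratic noise; memory-flavoured scores carry a small male
  disadvantage, which propagates into a male > female cognitive age gap.
  **Brain markers** load on age + u with targets spread over 0.21–0.55,
  a common factor (25%), TICV components on volumes, and additive APOE
  shifts on the Alzheimer's plasma markers. Variables destined for
  Box-Cox are generated on a log scale and exponentiated (the TMT B/A
  ratio is the exponential of a latent log-ratio of trail times); counts
  and questionnaire totals are rounded.
* **Lifestyle**: a 30-variable, K = 7 factor model with block-sparse
  loadings by domain (sleep, diet, physical activity, physical fitness,
  mental activity, cardiovascular risk, mental health, physical health),
  age/sex effects on a plausible subset (grip strength, muscle mass,
  eGFR, blood pressure, …) so the residualization stage has real work. A
  clean `block_loadings` matrix (single loading 0.7 per variable) is
  provided for strong-signal recovery experiments; the default matrix is
  deliberately weaker in factors 6–7.
* **Missingness** is MCAR only (per-cell rates: 11 lifestyle variables at
  3%, two at 11.4%, cognitive cells at 0.2%) plus whole-block
  availability (≈75% of subjects have brain markers, ≈61% the lifestyle
  assessment), mirroring a realistic visit structure. MAR/MNAR mechanisms
  are out of scope.

What passing tests on this generator do *not* show: robustness to
MAR/MNAR missingness, to non-linear age trajectories, to floor/ceiling
effects in test scores, or to realistic between-test correlation
structure beyond a single common factor — users needing those features
must supply their own loading and correlation structure.

## Problem sizes and determinism

Default experiment sizes: cohorts of n = 350 (population-calibration
checks use n = 5000), parallel analysis at 208 × 30 with 1000 iterations
in recovery experiments and 5000 in the pipeline, mediation recovery with
50 replications of n = 200 at 2000 draws, age-gap recovery over 10 seeds.
Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from one master seed and a rerun with identical
configuration reproduces artifact checksums byte for byte.

## Known limitations

* The bias-correction literature contains several variants; results are
  reported for the offset form, and gap magnitudes (not ranks) depend on
  that choice.
* PC scores enter regressions unscaled (variance = eigenvalue):
  coefficient magnitudes depend on this convention, p-values do not.
* The chained imputer is linear; strongly non-linear dependencies among
  lifestyle variables would favour a forest-based imputer.
* Horn retention counts are sample statistics, not ground truth — see the
  null-retention note above.
* On synthetic pipelines the PCA component paired with the generative
  mediating factor need not appear at the configured treatment index with
  a canonical sign; recovery tests align sign and scale against the
  stored factor scores before comparing.
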