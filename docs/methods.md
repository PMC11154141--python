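# Methods

## The analysis chain

The package estimates how a weighted lifestyle dementia-risk score (LIBRA)
relates to cognitive performance in a middle-aged population, and how much of
that association is carried by two brain markers: the brain-age gap (BAG)
derived from whole-brain MRI scalars, and white-matter connectivity
summarised as whole-brain average node degree. The chain is strictly
feed-forward: raw phenotype table → factor dichotomisation and weighted
scoring → brain-age model and per-participant BAG → composite cognition →
covariate-adjusted path system → effect decomposition.

### LIBRA score

Each factor is dichotomised at its published cut-off (diet score ≥ 6;
0 < alcohol < 70 g/week; MVPA < 150 min/week; current smoking; BMI ≥ 30;
SBP ≥ 140 or DBP ≥ 90 or antihypertensive medication; cholesterol ≥ 6.5
mmol/L; fasting glucose ≥ 7.0 or 2-h OGTT ≥ 11.1 or diabetes medication or
diagnosed T2DM; heart-disease history; eGFR < 60 or albuminuria; PHQ-9 ≥ 10
or interview-diagnosed depression) and contributes its weight when present.
Weights ship in `brainpath/data/libra_weights.yaml` and can be replaced from
the CLI. Cognitive activity (weight −3.2) is treated as unavailable by
default, so attainable scores span [−2.7, +12.7]. Tertile cut-points are the
empirical 1/3 and 2/3 quantiles taken at observed values with ties assigned
to the lower tertile; this makes the observed tertile ranges half-open from
above, matching how such ranges are conventionally reported.

Coding choices where the literature is ambiguous, all configurable in
`LibraConfig`:

- **Alcohol.** "Low-to-moderate" intake is the protective state; abstainers
  are coded *absent* by default (`abstainers_protective` flips this).
- **Smoking.** Current smokers only; former smokers are absent.
- **"Other" diabetes.** Diabetes status other than T2DM does not by itself
  satisfy the factor, though its glucose values or medication use may.
- **Missing fields** mark the factor unavailable with a warning; the pipeline
  enforces complete cases on the eleven assessed factors.

### Brain-age model

Calendar age is the outcome throughout; features are standardized (sample
SD, n−1), WMH volume is log-transformed as ln(1 + mL) to tolerate zero
lesion load, and count variables are dichotomised to presence. Model
building follows a three-step protocol: univariable ranking by |standardized
β| with P ≤ 0.05 (quadratic term flagged when its added coefficient reaches
P < 0.05), category-seeded multivariable Model 1 with backward pruning,
stepwise-extended Model 2, and a LASSO Model 3 over main effects, flagged
quadratics and all pairwise interactions. The LASSO penalty is chosen by
10-fold cross-validation with the 1-SE rule (fixed fold seed) and the
surviving terms are refit by OLS to remove shrinkage bias; at zero penalty
this reduces exactly to least squares (asserted to 1e-6 in the tests). The
most parsimonious model within a configurable R² tolerance (default 0.01) of
the best is selected.

BAG = predicted − calendar age, so a positive gap means an older-looking
brain. Two training-sample identities follow from least squares and are
asserted at 1e-8: mean BAG is zero, and BAG is orthogonal to every model
predictor. Whenever R² < 1, BAG correlates negatively with calendar age
(regression to the mean); the correlation is reported as a diagnostic and
all downstream models enter age as a covariate rather than residualising
BAG on age.

By default the pipeline's BAG model is built from the volumetric and
vascular features only. Folding average node degree into the brain-age model
would make BAG exactly orthogonal to it on the training sample (it becomes a
model predictor), mechanically erasing the BAG→connectivity pathway that the
mediation stage is designed to estimate; connectivity is therefore reserved
as a mediator in its own right (`include_connectivity_in_brainage` restores
the fully general behaviour).

### Path system and decomposition

The mediation engine fits one least-squares equation per endogenous
variable, each sharing the exposure and covariate set; for this recursive
linear system per-equation OLS coincides with maximum-likelihood SEM.
Mediators and outcome are standardized on the analytic sample. A tertile
exposure enters as 0/1 dummies against tertile 1 (y-standardized contrasts);
a continuous exposure is standardized (fully standardized coefficients).
Because every equation shares covariates and each later equation contains
all earlier mediators, the reduced-form total effect equals direct + Σ
indirect *exactly* — the suite asserts the identity at 1e-10, and asserts
path-tracing equivalence against brute-force enumeration of all directed
exposure→outcome paths on random systems.

Proportion mediated is indirect/total within the same fitted model. A zero
total returns NaN with a warning rather than ±∞; opposite-signed
indirect/total (inconsistent mediation) returns a negative percentage with a
warning. `decompose_serial(..., external_total=...)` supports ratios quoted
against a different model's total, a convention that appears in applied
reports.

Default inference is the first-order delta method (multivariate Sobel):
equation-level covariance matrices are used in full within equations and
treated as independent across equations, which is exact asymptotically for
recursive systems with independent errors. A nonparametric bootstrap
(percentile CIs, re-standardization inside every resample, degenerate
resamples skipped and counted) is available everywhere. In simulation the
delta and bootstrap SEs agree within a few percent; percentile CIs for weak
product terms run slightly below nominal coverage (~93–94% at n = 2000),
a known property of product-of-coefficients intervals. Under a partial null
(active exposure→mediator path, zero mediator→outcome path) the delta z-test
rejects at its nominal 5%; under the complete null the product statistic is
conservative, as expected. No multiple-testing correction is applied; P <
0.05 is the significance convention throughout.

Group interaction (effect modification) is tested by a Wald χ² on the block
of exposure-by-group product terms, df = number of product terms.

### Covariate sets

Two covariate sets are carried deliberately: the pre-path regressions adjust
for age, sex, education and glucose-metabolism status (the cohort's sampling
design oversamples type 2 diabetes), while the path systems adjust for age,
sex, education and the imaging-to-testing interval. Both are configurable in
`AnalysisConfig`.

## Synthetic cohort generator

The generator is the package's test bed and defines its reference study
conditions. It emulates a 40–75-year population (uniform ages, ~50% male,
~20% T2DM by design), draws eleven raw lifestyle measurements consistent
with their dichotomisation from an age-linked latent risk, and then builds
the brain and cognition variables from a linear-Gaussian structural model on
standardized latents, so every injected coefficient is an exact estimand:

| parameter | default | meaning |
|---|---|---|
| lifestyle→substrate | +0.13 | standardized effect of LIBRA on the brain-age substrate |
| lifestyle→connectivity | −0.05 | direct lifestyle effect on node degree |
| substrate→connectivity | −0.40 | older-looking brains are less connected |
| substrate→cognition | −0.13 | brain-ageing effect on latent cognition |
| connectivity→cognition | +0.06 | connectivity effect on latent cognition |
| lifestyle→cognition | −0.07 | residual direct effect |
| substrate scale | 11 y | SD of the brain-age substrate in years |
| vascular scale | 5 y | vessel-specific ageing beyond the substrate |
| domain loading | 0.92 | loading of each cognitive domain on latent cognition |

These defaults imply a tertile-3-vs-1 total effect on cognition of ≈ −0.20
SD with ≈ 18% mediated via BAG, and they were fixed once against that regime.
MRI scalars are smooth functions of an *effective brain age* (calendar age
plus 11 × substrate) with feature-specific measurement noise sized so that
no single scalar suffices: each informative volume carries ~3.5 years of
age-equivalent error alone but ~2 years in combination, which (i) puts the
brain-age model at R² ≈ 0.46, (ii) makes the fitted BAG a nearly
unattenuated substrate proxy (reliability ≈ 0.97), and (iii) forces the
stepwise protocol to retain several features. Vascular features (WMH, CMB,
infarcts) age along a partially distinct axis — the shared substrate plus a
5-year vessel-specific deviation — without which the CSF and WMH quadratics
are mutually substitutable and the multi-term selection pattern is not
identifiable. CSF expansion and lesion load accelerate with effective age
(quadratic terms); grey-matter atrophy is linear over this age range.
Microbleed counts follow a zero-inflated Poisson with age-increasing
presence probability, since only presence enters the models.

Two deliberate simplifications, and what they imply about test evidence:

- **Cognition has no direct age effect by default** (the slope is
  configurable). All age-relatedness of cognition flows through the modelled
  paths, which makes a fully-nulled configuration produce lifestyle scores
  and cognition that are *exactly* independent — the basis of the null
  calibration tests. Real cohorts have residual age effects; the covariate
  machinery is exercised, but its confound-removal is demonstrated on a
  milder dependence structure than reality's.
- **Factors are conditionally independent given the latent risk.** Joint
  factor correlations beyond a single shared axis are not represented, so
  passing tests say nothing about, e.g., cluster structure among
  cardiometabolic factors.

A scale subtlety, verified in simulation: the fitted BAG mixes the substrate
signal with a regression-to-the-mean age component of comparable size, so
*individual* standardized edges touching BAG are rescaled relative to the
injected coefficients (the exposure→BAG edge deflates, the BAG→outcome edge
inflates, and the factors cancel in products). Indirect effects, proportions
mediated and the lifestyle→cognition total are scale-invariant and recover
the injected values; edge-level recovery is therefore asserted on
`generate_path_dataset`, the generator's exact linear-Gaussian benchmark in
which the mediators are observed directly.

`generate_connectome` produces toy tract-count matrices (G(n, p) topology,
geometric counts, default 94 regions); `average_node_degree` applies the
≥ 2-tract noise-suppression rule before counting, and is asserted equal to a
brute-force per-node count and to an independent graph-library computation.

## Numerical and procedural choices

- Standardization uses the sample SD (n−1) computed on the analytic sample;
  standardizing is idempotent and constant columns raise errors (or, in
  brain-feature preprocessing, become flagged zero columns).
- Quadratic terms are squares of standardized features, not re-standardized.
- Rank-deficient designs raise an error naming the collinear columns
  (QR-based detection).
- Equation P values use the standard normal reference (z tests), matching
  SEM-style reporting; the brain-age model-building stage uses exact t/F
  references internally.
- Bootstrap resamples that produce a degenerate design (e.g. an empty
  tertile) are skipped and counted, never silently imputed.
- Ties at tertile cut-points go to the lower tertile.
- All randomness flows from explicit integer seeds; reports embed the seed.

## Problem sizes used by the test-suite studies

Replicate studies run at the sizes the package's own guarantees are stated
for: parameter recovery averages 200 replicates of n = 5000 (exact benchmark
and full pipeline); bootstrap coverage uses 250 replicates of n = 2000 with
400 resamples; interaction-test calibration uses 400 replicates of n = 800;
null-model calibration uses 200 replicates of n = 600. These sizes give
Monte-Carlo error comfortably inside the asserted bands while keeping the
default test run in the minutes range.

## Known limitations

- The path engine covers at most two serial mediators — the study design it
  serves — not arbitrary DAGs.
- No latent-variable measurement models, no longitudinal structures, and no
  sensitivity analysis for unmeasured confounding; estimates are
  associational on cross-sectional data.
- Percentile bootstrap CIs for weak products undercover mildly (see above);
  the delta method is the default inference for that reason.
- The generator's realism is structural, not distributional: marginal
  distributions of raw measurements are plausible but not matched to any
  particular cohort.
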