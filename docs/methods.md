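# Methods

`oculomse` implements a biomarker analysis for fixational eye-tracking:
multiscale fuzzy-entropy profiles of gaze position and mean pupil diameter
are extracted from short resting-fixation recordings, tested for group
differences, and combined in a penalized classifier.  This note documents
the models, the numerical choices, and what the synthetic cohort generator
does and does not emulate.

## Signal model and preprocessing

Recordings are binocular gaze position (degrees of visual angle) and pupil
diameter (mm) sampled at 300 Hz for ~2 minutes.  Preprocessing follows a
fixed order — segment, mask, exclude, interpolate, filter — so filters
never see missing data:

1. **Epoching.** Non-overlapping 10-s epochs (`epoch_s`, default 10);
   a trailing partial epoch is discarded.
2. **Blink masking.** A blink is any maximal run where an eye's validity
   flag is false or its reported pupil diameter is ≤ 0 (vendor-neutral
   semantics).  Each run is extended by `blink_pad_ms` (default 10 ms,
   i.e. 3 samples at 300 Hz) on both sides, because tracker flags lag the
   true lid closure.  Gaze and pupil share one mask — the union over both
   eyes — since blinks are binocular and the gaze signal is derived from
   both eyes.
3. **Exclusion.** Epochs with strictly more than `max_missing_frac`
   (default 50%) missing samples are dropped; an epoch at exactly the
   threshold is retained.  Per-participant exclusion fractions are
   reported in the QC table.  A participant with no surviving epochs gets
   missing features (the row is kept).
4. **Interpolation.** Interior gaps are filled linearly between flanking
   valid samples; leading/trailing gaps hold the nearest valid value
   (extrapolating a trend would invent signal).
5. **Filtering.** Gaze: 0.1–30 Hz band-pass (retains drift, microsaccades
   and the oculomotor band; suppresses slow head/posture drift and
   high-frequency noise).  Pupil: 5 Hz low-pass, DC preserved (the feature
   is the mean diameter).  Both are 4th-order Butterworth filters applied
   forward–backward (`sosfiltfilt`), chosen because zero-phase filtering
   does not displace saccade timing; the filter family/order is a
   conventional choice for physiological signals, not a tuned one.
   Sensitivity variants (2 or 4 Hz high-pass) are plain configuration
   changes (`eye_band_hz`).

## Fuzzy entropy and multiscale profiles

For a z-scored series of length N, delay vectors of length m are compared
under the Chebyshev distance and graded by the exponential membership
μ(d) = exp(−dⁿ/r); with φ_w the mean membership over all ordered pairs
i ≠ j of w-length templates,

    FuzzyEn(x; m, n, r) = −ln( φ_{m+1} / φ_m ).

Defaults m = 2, n = 2, r = 0.2.  Implementation details that matter:

* Both φ_m and φ_{m+1} are computed over the same template starts
  i = 1..N−m, which keeps the ratio well defined and the value
  non-negative up to floating error (the membership means then satisfy
  φ_{m+1} ≤ φ_m).
* The estimator follows the plain definition: template vectors are *not*
  re-centred by their local mean (some variants subtract it; this one does
  not).
* Each epoch is z-scored once, **before** coarse-graining, and the
  tolerance r is held fixed across scales — the standard multiscale
  convention, so coarser scales are measured against the original signal's
  amplitude scale.
* The O(N²) pairwise kernel runs in single precision for N ≥ 1024
  (error ~1e-7, orders of magnitude below sampling variability; verified
  against a double-precision definitional evaluation at shorter lengths to
  1e-12).
* A zero-variance series returns 0 (degenerate input, nothing to measure).

Coarse-graining at scale τ replaces the series by means of consecutive
non-overlapping windows of length τ, giving ⌊N/τ⌋ points; τ runs 1..30,
i.e. 0.003–0.1 s at 300 Hz — the time scales of tremor, microsaccades and
drift.  Per-scale values are averaged across a participant's retained
epochs and then natural-log transformed (FuzzyEn values are right-skewed);
the log is applied at the participant level, after epoch averaging.  The
classifier features are the means of the log profile over scales 1–10
(0.003–0.03 s) for each axis, plus the mean pupil diameter (temporal mean
per eye over retained filtered epochs, then averaged between eyes).

## IAAFT surrogate test

Surrogates preserve the amplitude distribution exactly and the power
spectrum approximately while randomizing Fourier phases, realising the
null hypothesis of a linear stochastic process under a static monotone
transform.  Each iteration imposes the original spectrum magnitudes and
then rank-orders the result onto the original values; the loop runs a
fixed 100 iterations (no early exit — determinism) and ends on the
amplitude step, so each surrogate is an exact permutation of the source.
Surrogates are generated per epoch — the unit on which FuzzyEn is
computed — with 10 surrogates per epoch from distinct child seeds, and
pushed through the identical coarse-grain/FuzzyEn path.  Per participant
and scale, the original log FuzzyEn is compared with the log of the
surrogate-ensemble mean by a paired t-test within each group;
Benjamini–Hochberg FDR is applied across the 30 scales with flags at
q < 0.05 and q < 0.01.  Negative t means the original is *less* entropic
than its linearized surrogate — the signature of regular nonlinear
structure.

## Group statistics

* **Repeated-measures ANCOVA** of the 30-scale log-FuzzyEn profiles:
  group (2 levels) as between-subject factor, scale as within-subject
  factor, age as covariate.  Implemented as the classical split-plot
  decomposition — between effects on subject means, within effects on an
  orthonormal contrast transform — with Type III sums of squares
  (effect-coded group, centred covariate).  Greenhouse–Geisser ε is
  estimated from the residual covariance of the repeated measures after
  removing the between-subject model, and multiplies the within-effect
  degrees of freedom.  Effect sizes are partial η² within each error
  stratum.  With a constant covariate the model reduces exactly to a
  mixed between-within ANOVA (verified against pingouin).
* **One-way ANCOVA** for scalar features (pupil size): group adjusted for
  age, partial η²; falls back to one-way ANOVA with a warning if the
  covariate is constant.
* **Post hoc per-scale t-tests**: independent two-sample Student
  (pooled-variance) tests by default — Welch by flag — with BH-FDR across
  the 30 scales.  They are not age-adjusted (they are descriptive
  follow-ups to the ANCOVA).
* **Severity correlations**: Pearson r of each feature against the ASRS
  total and subscale scores, in the ADHD group and its drug-naive subset;
  pairs with < 3 observations or zero variance are flagged undefined.
* **Power analysis**: the Fisher-z approximation
  n = ((z_{1−α/2} + z_{power})/atanh|r|)² + 3, reported as the exact
  ceiling and rounded up to the nearest ten.  For |r| = 0.36 at α = 0.05
  and 80% power this gives 59, i.e. ≈ 60 participants per correlation.
* **Demographics table**: mean ± SD and two-tailed pooled t-tests for
  continuous variables, Pearson χ² for the sex ratio, for both the
  TD-vs-ADHD and TD-vs-drug-naive contrasts.

## Classifier

Weighted L1-penalized logistic regression on standardized features:
minimize Σᵢ wᵢ·NLL_i + λ‖β‖₁ with the intercept unpenalized and per-sample
weights inversely proportional to class frequency, normalized to sum to n
(each class then carries total weight n/2).  Evaluation is a nested
cross-validation: an outer leave-one-out loop, and within every outer
training fold an inner stratified 5-fold loop that selects λ from a
deterministic log-spaced grid (default 50 points over 1e-4..1e2).
Reproducibility on a 36-participant sample argued for the grid over a
stochastic Bayesian search; the grid is configurable.  The inner criterion
is class-weighted cross-entropy on the validation folds (smooth,
threshold-free and defined for tiny folds; pooled inner AUC is available
by option); ties prefer the largest penalty.  Standardization constants
and λ are computed from training folds only — a perturbation audit in the
test suite verifies that changing a held-out participant's features never
changes that fold's penalty choice.

Pooled out-of-fold probabilities give one ROC curve (trapezoidal AUC; tied
scores split, so constant probabilities give exactly 0.5) and one PR curve
(step-integrated AUC, i.e. average precision).  The operating threshold is
the probability cut maximizing F1 over all achievable operating points,
ties resolved to the lowest threshold (favouring sensitivity); sensitivity,
specificity and the confusion matrix are reported at that cut.  The
feature-combination sweep evaluates all 7 non-empty subsets of
{pupil size, horizontal entropy, vertical entropy} under the identical
protocol and seed.

Known small-sample behaviour: pooled leave-one-out AUC is slightly
pessimistic under the null (a held-out participant's class is
under-represented in its training fold), so single null cohorts at n = 36
occasionally score below 0.45; the across-cohort mean stays at chance.

## Synthetic cohort generator

The generator produces recordings with the statistical structure the
analysis assumes, so the full pipeline is testable without clinical data.
Gaze per axis is the sum of

* Ornstein–Uhlenbeck drift (diffusion 0.01 deg²/s, reversion 5 s⁻¹ —
  a stationary wander of ≈ 2 arcmin SD around fixation),
* microsaccades as a renewal process: Gamma inter-saccade intervals whose
  coefficient of variation (`isi_regularity`) tunes timing regularity,
  each event an instantaneous step (random direction; Gamma amplitude,
  mean 0.3°, CV `microsaccade_amp_cv`) relaxing exponentially (τ = 80 ms),
* sinusoidal tremor at 80 Hz and 0.004° (above the 30 Hz band edge, so it
  is attenuated as real ocular tremor would be), and
* white tracker noise (0.05° SD).

Pupil is baseline + hippus sinusoid (0.2 Hz, 0.1 mm) + per-eye noise;
blinks are binocular invalid spans (Poisson onsets at 8/min, uniform
100–300 ms durations) during which the tracker reports no diameter.
Between-participant heterogeneity: the individual pupil baseline is drawn
with SD 0.4 mm, and oculomotor parameters get multiplicative lognormal
jitter (CV 0.2).  Covariates (age, sex ratio, ASRS subscales; total =
inattentive + hyperactive subscores) are drawn from group-matched
truncated Gaussians.

The clinical contrast is built in by construction.  The ADHD-like group
has more frequent (1.8 vs 1.2 s⁻¹), larger (0.45° vs 0.3°), temporally
regular (ISI CV 0.15 vs 0.6) and stereotyped (amplitude CV 0.1 vs 0.5)
microsaccades — a more predictable trace, hence lower multiscale entropy,
consistent with reports of increased, regular microsaccades and larger
gaze dispersion in ADHD — and a 0.4 mm larger pupil baseline.  The
entropy deficit is scale-dependent: it is concentrated at the fine scales
(1–10) that form the classifier features and attenuates — slightly
reversing — at coarse scales, because structured signals retain entropy
under coarse-graining while noise-dominated ones lose it.  In a 30-scale
repeated-measures ANCOVA, simulated cohorts therefore show a strong
group × scale interaction rather than a scale-wide group main effect.  With the
0.4 mm between-subject SD this yields a pupil effect of d ≈ 1 and an
entropy effect of d ≈ 1.5 at the default sizes, comparable to the effect
sizes the analysis is designed for.  What the generator does **not**
emulate: saccade main-sequence kinematics, medication effects,
head-motion artifacts, gaze-position-dependent pupil foreshortening, or
any dependence of covariates on the eye-movement signal.  Passing
end-to-end tests therefore demonstrates that the pipeline recovers effects
of this kind and size from signals with realistic sampling structure — not
that real ADHD recordings behave this way.

## Problem sizes used in tests

The default configuration (2-minute recordings, 12 epochs, 30 scales,
10 surrogates × 100 iterations, 50-point λ grid) is what the pipeline runs
in production.  The test-suite and acceptance-script simulations use the
same protocols at reduced sizes, chosen so the checked contrasts remain
well-powered: surrogate-test calibration on 100 cohorts of 5 AR(1) series
(420 samples each); classifier null behaviour on 100 cohorts at the full
20/16 group sizes; end-to-end parameter recovery on 25 cohorts of 20/16
participants with 15-s recordings cut into 5-s epochs and a 6-point λ
grid.  The entropy estimator's oracle equivalence is asserted at lengths
50–500, where the double-precision path is exact to 1e-12.

## Known limitations

* The rm-ANCOVA's Greenhouse–Geisser ε uses the pooled residual
  covariance (SPSS-style); packages that estimate ε from the grand
  covariance differ in the third decimal.
* FuzzyEn of very short coarse series (τ = 30 on one 5-s epoch → 50
  points) is noisy; profiles at large τ should be read with that in mind.
* The lasso path is solved by liblinear with a large intercept-scaling
  constant; the intercept penalty is ~1e-3 of a coefficient's, negligible
  but not exactly zero.
* Pooled-LOOCV AUC bias under the null (above) is a property of the
  evaluation protocol, not of the implementation.
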