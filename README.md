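# oculomse

Multiscale-entropy eye-movement and pupillometry biomarkers from
fixational eye-tracking recordings.

Involuntary fixational eye movements — drift, microsaccades, tremor — are
controlled by a widely distributed oculomotor network, and the pupil's
baseline diameter indexes the locus coeruleus–norepinephrine arousal
system.  Both are altered in adult ADHD: fixational traces become more
temporally *regular* (lower entropy) and baseline pupils larger.
`oculomse` implements the full analysis that turns raw 300 Hz binocular
recordings of a 2-minute fixation task into these biomarkers and evaluates
their diagnostic value:

1. **Preprocessing** — 10-s epochs, blink masking (±10 ms pad), exclusion
   of epochs with > 50% missing samples, linear interpolation, 0.1–30 Hz
   gaze band-pass and 5 Hz pupil low-pass (zero-phase Butterworth).
2. **Multiscale fuzzy entropy** — FuzzyEn(x; m, n, r) = −ln(φ_{m+1}/φ_m)
   with the exponential membership exp(−dⁿ/r) on Chebyshev template
   distances (m = 2, n = 2, r = 0.2), computed on coarse-grained copies of
   each epoch at scales τ = 1..30 (0.003–0.1 s); participant features are
   the mean log FuzzyEn over scales 1–10 per axis plus the mean pupil
   diameter.
3. **IAAFT surrogate testing** — per-scale paired comparison of each
   recording against 10 iterative amplitude-adjusted Fourier-transform
   surrogates (100 iterations), with Benjamini–Hochberg FDR across scales:
   a test for nonlinear temporal structure.
4. **Group statistics** — repeated-measures ANCOVA (group × scale, age
   covariate, Greenhouse–Geisser correction), one-way pupil ANCOVA, post
   hoc per-scale t-tests with FDR, severity correlations, demographics
   table, and a Fisher-z power calculation.
5. **Classification** — class-weighted L1 (lasso) logistic regression
   evaluated by nested leave-one-out cross-validation with inner
   stratified 5-fold penalty tuning, ROC/PR curves, and the F1-optimal
   operating threshold, swept over all feature combinations.
6. **Synthetic cohorts** — a generator of realistic recordings
   (Ornstein–Uhlenbeck drift, renewal-process microsaccades with tunable
   regularity, tremor, blinks, hippus) with the ADHD-like contrast built
   in, so the entire pipeline is testable without clinical data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Sweep all feature combinations on a 20 + 16 participant feature table with
a 0.4 mm pupil offset and a 0.3 log-unit entropy deficit in the ADHD-like
group (`examples/05_classification.py`):

```
features                                    AUC-ROC  AUC-PR     F1   sens   spec
pupil_size+vert_fuzzyen                       0.906   0.801  0.889   1.00   0.80
pupil_size+hor_fuzzyen+vert_fuzzyen           0.887   0.787  0.833   0.94   0.75
pupil_size                                    0.875   0.742  0.857   0.94   0.80
pupil_size+hor_fuzzyen                        0.850   0.710  0.811   0.94   0.70
hor_fuzzyen+vert_fuzzyen                      0.822   0.779  0.788   0.81   0.80
hor_fuzzyen                                   0.787   0.696  0.750   0.94   0.55
vert_fuzzyen                                  0.738   0.677  0.732   0.94   0.50
```

Each row is one lasso model evaluated on pooled leave-one-out
probabilities: a pupil + entropy pair tops the sweep (complementary
information), while the two redundant entropy features together rank below
it.  Sensitivity/specificity are read at the PR-curve point that maximizes
F1.  The group-statistics example (`examples/04_group_stats.py`) prints,
for a simulated cohort with a fine-scale entropy deficit:

```
pupil ANCOVA: F=6.471, p=0.0158, partial eta^2=0.164
rm-ANCOVA group: F=63.851, p=0.0000, eta^2=0.659
rm-ANCOVA group_x_scale: F=5.348, p=0.0000, eta^2=0.139, GG eps=0.495
post hoc t-tests: scales flagged at q<0.05: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
n to detect |r|=0.36 at 80% power: 59 (~60)
```

The flagged scales recover exactly the injected deficit (scales 1–12), and
the power line shows why a 16-participant group cannot confirm a modest
severity correlation — roughly 60 cases would be needed.

The other examples build a cohort (`01`), compute one participant's
entropy profile (`02`) and run the surrogate nonlinearity test (`03`).
The end-to-end pipeline is also available as a thin CLI:

```bash
oculomse run-all --out output --seed 1        # simulate -> ... -> classify
oculomse simulate --recordings-dir rec --manifest manifest.csv
```

Stages exchange plain CSV/JSON artifacts, each carrying the configuration
hash and seed in a provenance header.

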