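# Methods

## The prediction problem

For a decedent cohort, every laboratory panel drawn within `window_days`
(default 365) of death is a sample. For a horizon of `n` months a sample is
an *event* if it was drawn within `n × month_days` of death and a *control*
otherwise; `month_days` defaults to 30.4375 (365.25/12), and both the
window and the event boundary are closed (`0 ≤ d ≤ 365`; event ⇔
`d ≤ n·month_days`). A calendar-month convention would be equally
defensible; the choice is configurable and only moves a handful of samples
near the boundaries. Event sets nest across horizons by construction, and
every in-window sample receives exactly one label per horizon.

This "time-inclusive" design multiplies the effective sample size (tens of
time points per patient) at the cost of within-patient correlation between
samples. The package follows the source method in treating samples as
exchangeable during fitting; the train/test split is at the *patient*
level, so test-set performance is still free of patient leakage.

## Panel filtering

Items measured at fewer than `min_coverage` (default 50%) of all distinct
(patient, date) time points — infrequently ordered tests such as tumor
markers — and urine-based items are excluded. The coverage boundary is
closed (exactly 50% is retained). Filtering is idempotent.

## Model fitting

Each candidate model is a logistic regression on k raw laboratory values
(default k = 3). Fitting maximizes the ridge-penalized log-likelihood with
penalty `λ/2·‖β‖²` on *standardized* slopes, intercept unpenalized;
`λ = 0.01` by default — enough to guarantee existence and uniqueness under
complete separation while leaving coefficients essentially unshrunken at
the sample sizes involved. The regularizer runs on internally standardized
features for conditioning and reports coefficients back on the raw item
scale, so a coefficient reads "per g/dL of albumin". The optimizer is
Newton/IRLS with backtracking line search, converged when the Newton step
falls below 1e-11 on the standardized scale; with k ≤ 4 this takes a
handful of quadratically convergent iterations and makes the fit invariant
(to ≈1e-8 on raw coefficients) under sample reordering and affine
rescaling of items. A zero-variance column contributes a zero slope rather
than an error. The test suite cross-checks the fit against an independent
ridge-logistic implementation (scikit-learn, `C = 1/λ`) on the same
standardized objective.

Class imbalance: before fitting, the minority class of the training labels
is oversampled — every original sample is kept and minority indices are
redrawn uniformly with replacement until the classes are equal — giving
prevalence exactly 0.5. PPV, NPV and accuracy on the *test* cohort are
computed on the same kind of balanced resample, which makes them comparable
across horizons with different event rates and ties them to
sensitivity/specificity through the closed forms
`ppv = sens/(sens+1−spec)`, `npv = spec/(spec+1−sens)`,
`acc = (sens+spec)/2`. AUC is rank-based and always computed on the
original, unresampled test scores.

Missingness: per-combination complete-case analysis. No imputation or
carry-forward — routine-panel items are usually drawn together, and a
3-item model is only applicable at time points where its items exist.

## Search and selection

All `C(|panel|, k)` combinations are enumerated in lexicographic order and
fitted at each horizon (40 items, k = 3: 9,880 combinations, 59,280
models). Per horizon, models are ranked by test-cohort AUC (ties break
lexicographically on items, so rankings are deterministic); the ROC curve
on the test cohort also supplies each model's classification cutoff via
Youden's J (`max tpr − fpr` over observed score thresholds, ties to the
smallest threshold — with balanced training the resulting cutoffs cluster
near 0.5). Across horizons, the family is chosen by minimum rank-sum, ties
broken by higher mean AUC then lexicographic items. The rank-sum rule is
this package's formalization of "best or second-best at every horizon";
any reasonable aggregation agrees when one family dominates. Combinations
that cannot be fitted (a class absent among complete cases) are recorded
and excluded from ranking rather than aborting the sweep.

The published model set (six horizons, shared Alb/LDH/Neu triple, printed
coefficients and cutoffs) is bundled as data and applied without
refitting; external validation applies fixed coefficients and cutoffs to
an independent, separately assembled cohort, optionally skipping horizons
(e.g. the 6-month model for a cohort censored at 180 days). The boundary
`p = cutoff` classifies as event. Published LDH and neutrophil units are
not stated by the source; predictions are meaningful only in the original
laboratory's units, and the predictor itself is unit-agnostic (coefficients
are per item unit).

## The synthetic cohort generator

The generator emulates the structural features the method relies on, not
any particular hospital's value distributions:

- **Trend shape.** Each item's mean is
  `baseline + shift·exp(−d/τ)` where `d` is days to death: flat at
  baseline far from death, approaching `baseline + shift` at death.
  `τ = 60 days` for the signal items, matching a gradual, accelerating
  terminal change. Albumin: 4.0 g/dL baseline, shift −1.5; LDH: 200 U/L,
  shift +180; neutrophils: 60% of leukocytes, shift +15. 37 further
  routine-panel items (CBC, chemistry, coagulation) at plausible adult
  reference values carry zero shift.
- **Sampling pattern.** Per-patient panel dates with exponential
  inter-panel gaps (mean 8.5 days, minimum 1 day, ≈43 panels/patient-year),
  truncated to the one-year window; item-level missingness at rate 0.25
  per (panel, item), mirroring ≈30 of 40 items present per time point.
- **Noise.** Per-patient Gaussian baseline offsets plus per-measurement
  Gaussian noise, truncated at the physiologic floor of zero. Heavy tails,
  unit drift, tumor-type-specific trends and censored (alive) patients are
  deliberately out of scope.

Identical configuration and seed give bit-identical tables.

What passing tests on this generator do and do not show: they verify the
*machinery* — labeling, balancing, fitting, ranking, selection — recovers a
known signal under realistic sampling/missingness; they do not calibrate
performance to real cohorts, whose AUCs are lower (synthetic signal items
here are cleaner than real biology; the 1-month synthetic AUC ≈ 0.97
versus ≈ 0.85 reported for real data).

**Selection recovery under these defaults.** Albumin and LDH are strong
markers (terminal shift ≈ 3 within-patient SDs) and always surface;
neutrophils are moderate (≈1.3 SDs), so the third model slot is contested
by null items within ≈0.004 AUC. At the standard study conditions
(500 patients, 12-item panel, full 220×6 sweep) the rank-sum selection
returns the exact triple in about three quarters of independent
replicates, and its coefficient signs match the generative directions in
all of them. This is a genuine property of one moderate marker beside two
dominant ones, not a machinery defect.

## Numerical and reporting conventions

- ROC follows the `score ≥ threshold ⇒ event` rule; curves include both
  endpoints, and the trapezoidal AUC equals the concordant-pair statistic
  with ties counted ½ — exactly, which the tests verify against brute-force
  pair counting.
- Trajectory summaries bin observations by days-to-death into 30-day bins
  with mean ± 1.96·SE; bins with n < 2 report undefined CIs.
- Metrics are rounded to 3 decimals at reporting time only.
- Balanced-evaluation resampling and every other stochastic step take
  explicit seeds; sub-streams are derived via CRC32 of (seed, horizon,
  items), so validating a cohort reproduces search-time metrics bit for
  bit when given the same seed.
- Problem sizes used by the test and acceptance runs — 500-patient
  cohorts, 12-item panels, five replicate sweeps — are the package's
  standard synthetic study conditions; they keep a full sweep around ten
  seconds while leaving event counts in the hundreds per horizon.

## Known limitations

- Decedent-only design: controls are samples from patients who *did* die,
  later; the models discriminate imminence of death among terminally ill
  patients, and say nothing about patients who survive.
- Within-patient correlation is ignored during fitting (as in the source
  method); standard errors of coefficients are therefore not reported.
- λ is fixed, not tuned; elastic-net/L1 variants, interactions and splines
  are out of scope.
- AUC confidence intervals (DeLong), calibration and decision-curve
  analysis are not implemented.
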