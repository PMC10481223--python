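# Methods

## Sensor model

The device measures conductance *G* (mS) of a small milk sample between
two fixed electrodes (cell constant *K* = 1 cm⁻¹) plus sample temperature.
Conductivity is σ = *G·K* (mS/cm). Two corrections follow:

* **Temperature compensation.** Aqueous electrolyte conductivity rises
  roughly linearly with temperature; we use
  σ₂₅ = σ_T / (1 + α(T − 25)) with α = 0.020 °C⁻¹, the conventional
  coefficient for KCl-like solutions. α is a per-device calibration field;
  the correction is exact against its own forward model and rejects
  temperatures where the denominator is non-positive (below roughly
  −25 °C at the default α, far outside the validated 0–50 °C range).
* **Per-device calibration.** Each device's distortion is modelled as
  affine, measured = gain·true + offset, fitted by least squares to KCl
  standard readings (defaults: 1.413 and 12.88 mS/cm, the 0.01 M / 0.1 M
  standards). With exactly two distinct standards the fit is exact, so a
  two-point calibration inverts the distortion to numerical precision.
  Fitted gains must be positive; post-calibration conductivities ≤ 0 are
  clipped to zero and *flagged* (`non_physical`) rather than raised, so a
  corrupt reading cannot abort a batch run.

## The MM% score

MM% maps σ₂₅ to a 0–100 scale from colostrum (high conductivity, 0 %) to
mature milk (low conductivity, 100 %). The deployed system uses a
proprietary empirical equation; this package substitutes a documented
surrogate:

    mm = 100 · w((σ_colostrum − σ) / (σ_colostrum − σ_mature))

with w the identity (default) or a rescaled logistic warp that preserves
the anchors exactly. Default anchors are σ_colostrum = 6.0 and
σ_mature = 3.0 mS/cm — consistent with the synthetic cohort, *not* claimed
as device constants. Every downstream computation (charts, classification,
screening) depends only on monotonicity and the [0, 100] range, so
replacing the surrogate with a production equation changes no interfaces.
Values outside [0, 100] are clipped and flagged, since noise around the
anchors is expected; whether a real device reports soft or hard saturation
above 100 % is unknowable from the outside, and hard clipping matches the
observed flat plateau in normative data.

## Classification rules

Scans are labelled retrospectively from reported data only (no direct
supply measurement), with precedence low_supply > bf_problems > normal:

* **L1** provider-recorded partial/mostly-formula feeding, formula in the
  previous 24 h, and at least one supply-associated tag (latch problem,
  tongue tie, low/slow weight gain, low milk supply) → `low_supply`.
* **L2** mother-reported low-milk-supply or slow-weight-gain indicators
  with > 20 % of daily feeds as formula → `low_supply`. The source
  description is ambiguous about whether the weight-gain indicator must
  co-occur with significant formula; we require the formula fraction in
  both branches, reading the sentence as (indicators) AND (> 20 %
  formula). This is the one rule whose reading is genuinely open.
* **B1** partial feeding (formula in the prior 24 h) with *no* tags →
  `bf_problems`. The 24 h window matches L1 (a "34 hours" variant in the
  source description is presumed a typo); the window is configurable.
* **B2** predominant (≥ 80 % own-milk) feeding that nevertheless carries
  supply-associated tags → `bf_problems`.
* **N1** exclusive / full / full-own-milk / predominant feeding without
  supply-associated tags → `normal`. Breast and nipple pain are separate
  conditions and never trigger supply rules.

Anything else is `unclassified`. The classifier is total, deterministic,
order-independent, and exhaustively tested against an independently coded
decision table. Contradictory records (e.g. exclusive feeding plus formula
in the last 24 h) are validation errors collected into a rejects report at
CSV ingestion.

## Reference chart

Normal-class scans are binned by continuous day postpartum (scan minus
birth over 24 h): daily bins [d, d+1) for d = 0…20, then
[21,28), [28,35), [35,45), [45,60), [60,∞). The coarse 21–60-day edges are
config-overridable (the source scheme only fixes "7–10-day" widths).
Percentiles (15/50/85) are empirical quantiles with linear interpolation
between order statistics. Smoothing: bins starting at day ≤ 2 draw from
[start − 1, end + 1); later bins from [start − 1, end). The trailing-only
extension was chosen over a leading truncation, which would discard the
bin's own records; disabling both offsets reduces the chart to a naive
per-bin quantile, which the tests verify bit-for-bit. Bins with fewer than
`min_n` = 5 windowed records are emitted as missing rather than as
degenerate percentiles. Charts serialize to CSV plus a JSON sidecar
carrying the config hash; reloading is bit-exact.

Screening is strict: a scan flags `below` only if mm < the day-matched
15th-percentile value; equality counts as `at_or_above`; missing bins
propagate as `no_reference` and are excluded (with counts logged) from
both numerator and denominator of sensitivity and specificity. The day
6–20 evaluation window is implemented as day ∈ [6, 21).

Group comparison fits a fixed-effects two-way ANOVA (class × day range) on
MM% via statsmodels, with Tukey HSD applied to the class factor within
each day range (the interaction-style post-hoc); with a single range it
degenerates to one-way ANOVA, which equals the pooled two-sample t-test
for two classes (F = t², asserted in tests).

## Synthetic cohort

The generator emulates the study conditions the analysis assumes, per
breast:

    σ(t) = σ∞ + (σ_colostrum − σ∞) · exp(−(t − t₀)₊ / τ)

* **Class kinetics.** τ defaults: normal 1.5 d, bf_problems 3.0 d,
  low_supply 5.0 d; onset t₀ defaults 0.5 / 1.0 / 2.0 d. Per mother, τ and
  t₀ are lognormal around the class default (log-sd 0.2 and 0.25); each
  breast jitters the onset by N(0, 0.25 d), emulating observed per-side
  asymmetry. A single-exponential approach to plateau is the simplest
  shape matching the described dynamics (steep rise, moderate rise,
  plateau).
* **Mature plateau.** σ∞ is lognormal with median 0.9·σ_mature (log-sd
  0.05). Mature-milk conductivity varies between mothers, and placing the
  100 %-anchor in the *upper* range of mature milk means the score
  saturates (clips at 100) for most fully mature samples — which is what
  produces the flat ~100 % plateau seen in normative charts. Without this
  margin the median curve would approach 100 only asymptotically.
* **Measurement.** Measured conductivity is σ(t)·(1 + ε), ε ~ N(0, 0.05)
  (the device's coefficient of variation), at a temperature drawn
  U(20, 37) °C with the forward temperature distortion applied, then a
  per-device affine gain/offset (gain U(0.95, 1.05), offset
  U(−0.1, 0.1) mS/cm across 8 devices). Matching KCl standard readings
  are emitted so the pipeline's calibration stage can invert the
  distortion; with noise off, the full chain is exact. Stored MM% is
  quantized to the 0.1 % display resolution.
* **Collection modes.** 6.25 % of mothers self-track (8–42 scans over
  ~30 d, one random breast per scan, reporter = mother); the rest receive
  1–2 provider visits (day ~ lognormal, median 8 d, log-sd 0.9; both
  breasts scanned, reporter = provider), mirroring the two real-world
  collection channels and their volumes.
* **Labels.** Feeding status, formula fraction and problem tags are drawn
  per mother to satisfy the classifier's decision table for the true
  class, so classification recovers ground truth exactly; a label-noise
  probability (default 0) replaces a mother's metadata with another
  class's to test robustness.
* **Class mix** defaults to 0.5 / 0.2 / 0.3 (normal / low_supply /
  bf_problems), echoing the real cohort's imbalance; default cohort size
  is 200 mothers (roughly 1,000 scans), which keeps full-pipeline runs
  under a second while giving every daily bin enough records.

What the generator does *not* emulate: inflammation/mastitis conductivity
spikes, preterm subgroups, pump-versus-feed sampling, missing or
inconsistent self-reports, day-dependent feeding-status changes within a
mother, and selection bias of a self-volunteered population. Passing
statistical tests on this cohort therefore demonstrates internal
consistency of the pipeline under its stated model, not clinical
performance on real data; in particular the synthetic sensitivity
(~60–80 % across seeds) is not a validation of the published 81 %.

## Kinetics recovery

`recover_kinetics` fits mm(t) = clip(P·(1 − exp(−(t − t₀)₊/τ)), 0, 100) by
nonlinear least squares (multi-start trust-region, free plateau P since
the score may saturate). Because sensor noise is multiplicative in
conductivity, the MM%-scale error shrinks as milk matures; residuals are
therefore weighted by the model-implied conductivity
(∝ 1/(anchor_ratio − mm/100), anchor_ratio = σ_colostrum/(σ_colostrum −
σ_mature) = 2 at the default anchors). Weighting leaves noise-free fits
exact. Requires ≥ 4 scans spanning ≥ 5 days; identifiability is best when
the series covers both the rising phase and the plateau. The recovery
benchmark uses slow-activation series with 12 scans evenly spanning days
0.5–20, i.e. a three-week self-tracking schedule.

## Numerical conventions

* Day bins and windows are half-open [start, end); day postpartum is a
  continuous float, 0-based at the birth datetime.
* Displayed sensitivities round half away from zero to integer percent;
  full precision is always stored.
* Quantiles use numpy's linear-interpolation estimator.
* All simulation randomness flows from a single integer seed through one
  `numpy` Generator; identical configs produce byte-identical CSVs.
* Config provenance is a SHA-256 hash (16 hex chars) of the canonical
  JSON serialization, stamped into chart sidecars and run reports.
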