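# Methods

This note documents the statistical procedures the package implements,
the simulator that stands in for raw device data, the numerical choices
made where the design was genuinely open, and what the test suite does
and does not demonstrate about real data.

## Epoch model

The unit of analysis is the wall-clock minute, a half-open window
`[t, t+60 s)` with `t` minute-aligned. Alignment to the clock (rather
than to the first sample) matches how consumer trackers expose by-minute
logs. A 60-s sample is assigned to the minute containing its timestamp
(floored), never split across minutes.

A heart-rate value of 0 is the single "no valid reading" encoding —
device off-wrist, dropout, or no row at all. Zeros never contribute to
any aggregate: the reference value for a minute is the mean of its
*nonzero* 10-s samples. Averaging zeros in would bias the reference
downward by tens of bpm whenever a single tick dropped out. The number
of contributing samples is retained per epoch, so a stricter filter
(e.g. require all six 10-s ticks: `min_reference_samples=6`) is a
configuration choice, not a code change. The default of 1 keeps free-
living data usable, where dropouts are routine.

Common wear — the inclusion rule for all paired analyses — is a minute
with nonzero epoch values on both devices. Everything else is excluded
outright. No imputation is performed anywhere; missingness in wearable
streams is strongly informative (nonwear), and imputing it would
manufacture agreement.

"Possible epochs" in the attrition log are the minutes spanned by either
device's stream (union of spans). This is an artifact convention chosen
for auditability; other definitions (session length, intersection of
spans) would change the denominator but not any downstream statistic.

## Zone classification

Relative intensity is `hr / (220 − age)` with age in years, unrounded;
fractional ages are accepted. A minute at or above 50% of the
age-predicted maximum is MVPA; the boundary is inclusive (≥). The two
zones are exhaustive for any positive heart rate; there is deliberately
no vigorous sub-zone. For the detection contingency table each device is
classified from its own value with the same participant age; for
stratified agreement the *reference* value defines the stratum, since
the reference is the intensity ground truth.

## Agreement statistics

**Mean difference.** `d_i = test_i − reference_i` (negative = the
tracker underestimates), summarised by the mean with a paired-*t*
two-sided 95% CI and p value. When the differences are constant the SE
is 0 and the t statistic undefined; the result is flagged degenerate and
reported as NaN, never silently as 0 or significance.

**ICC.** Single-measure, two-way, absolute-agreement intraclass
correlation — ICC(A,1) in McGraw & Wong's taxonomy — with subjects =
paired minutes and raters = the two devices:

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

where MSR, MSC, MSE are the row, column and residual mean squares of the
n×2 table without replication. The 95% CI uses the standard F-based
procedure for this form (Satterthwaite degrees of freedom for the
denominator). The implementation is validated three ways: against a
brute-force double-loop sums-of-squares oracle (tolerance 1e-10, 200+
random tables), against `pingouin.intraclass_corr`'s ICC(A,1) row, and
through the definitional properties (perfect agreement → 1; a constant
offset never increases it; absolute ≤ consistency form under offset).

The "overall" coefficient pools epochs across participants; pooling
ignores within-participant autocorrelation of consecutive minutes, which
makes the paired-*t* inference anticonservative. This mirrors standard
practice in device-validation analyses and is retained deliberately;
per-participant results are exposed alongside as the remedy. No
clustered or repeated-measures Bland–Altman variance correction is
applied, for the same reason — a documented limitation, not an
oversight.

**Strength labels.** weak < .5, strong > .7. The closed interval
[.5, .7] is labelled moderate — the conventional verbal rule leaves the
two boundary points formally ambiguous, and assigning them to the middle
category is the conservative reading.

**Bland–Altman.** Bias ± 1.96·SD of the differences (large-n normal
form, not a t quantile), with per-pair (mean, difference) coordinates
emitted for plotting.

**Deciles.** Pairs are rank-ordered by reference mean (ties broken by
timestamp then participant id, for deterministic output) and split into
10 groups differing in size by at most one; each group is summarised by
five-number statistics for reference means, test values, and reference
within-minute range widths.

## Detection and free-living metrics

MVPA is the positive class and the reference the truth standard:
sensitivity = TP/(TP+FN) over reference-MVPA minutes, specificity =
TN/(TN+FP), PPV and NPV column-wise. Metrics are stored as exact
integer ratios; a zero denominator yields an explicit undefined (None),
and rounding happens only in the report layer (one decimal for
percentages, two where finer precision is conventional for NPV-style
values; average daily MVPA minutes round half-away-from-zero for
display).

A valid wear day has ≥ 600 nonzero minutes (inclusive boundary) within
one calendar day, local midnight to midnight. Day summaries always
partition the 1440 minutes into no-reading / low / MVPA counts —
conservation is enforced by the type, not just tested. Only valid days
enter the free-living summaries. The adherence curve indexes days from
each participant's first valid day and reports, per index, the number of
participants contributing a valid day and the mean ± SD of worn minutes
(SD is NaN with a single contributor, not 0).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not cardiovascular physiology.

**Truth process.** A semi-Markov chain over four states — rest, light
activity, MVPA bouts, nonwear — with exponential dwell times (means 25,
5, 5, 4 min) and a fixed embedded transition matrix. Each bout draws a
target intensity uniformly from its state's band, expressed as a
fraction of the participant's `220 − age`: rest 0.28–0.36, light
0.34–0.44, MVPA 0.65–0.85. The realised heart rate lags the target
exponentially (τ = 20 s, so ~95% of a step is absorbed within a minute,
emulating post-exercise lag) and carries mean-reverting AR(1)
variability with ~2 bpm stationary SD. Nonwear emits no heart rate, and
the process restarts at the target after a gap.

**Device observation.** The reference reads the truth every 10 s plus
N(0, 1.5²) bpm noise; the test device reports each minute's true mean
plus `β0_i + β1_i·max(0, mean − rest_i)` plus N(0, 3²) bpm, with
participant effects `β0_i ~ N(−4, 1.2²)` bpm and
`β1_i ~ N(−0.15, 0.05²)`. Readings are rounded to integers and floored
at 25 bpm; per-reading dropout (3%/min test, 2%/tick reference) and
nonwear emit 0. Rest heart rate is drawn per participant from N(65, 6²)
truncated to [50, 85] bpm — a plausible adult range, a package constant.

**Calibration.** The error-model means (−4 bpm intercept, −0.15 slope)
reproduce the intensity-dependent underestimate the analysis is designed
to detect: with rest near 65 bpm and MVPA bouts around 75% of maximum
(~146 bpm for a 25-year-old), the expected biases are ≈ −4.2 bpm in the
low zone and ≈ −16 bpm in the MVPA zone; the low-zone activity bands
were placed near rest precisely so the slope term contributes little
there. The intercept SD of 1.2 bpm keeps between-participant
heterogeneity visible while a 10-person cohort mean stays near the
structural value. With these dwell parameters roughly 7% of worn time is
MVPA, which puts the free-living MVPA share in the low single digits of
total epochs.

**Study design defaults.** Ten participants, ages N(25.4, 3.7²)
truncated to [18, 65]; one validation session of 3–6 h with both
devices; 30 follow-up days with the test device only. Day-level
compliance decays geometrically (hazard 0.01/day), and a worn day covers
~1050 (SD 150) contiguous minutes placed uniformly in the day, so nearly
all worn days clear the 600-min rule but short-wear days occasionally do
not.

**Determinism.** All randomness flows from one integer seed through
spawned, per-participant, per-device RNG streams: a fixed seed is
bit-reproducible, and enlarging the cohort never perturbs existing
participants. Ground truth (β0_i, β1_i, rest HR, per-minute true means,
true zone minutes, worn days) is retained for recovery tests.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: PPG motion artifacts and spike noise,
skin-tone and fit effects, arrhythmia, the difference between pulse rate
and electrical heart rate, accelerometry, or any specific device's
firmware smoothing. Consequently raw-data-dependent magnitudes (an
overall ICC of a particular value, a particular sensitivity) are
properties of the simulated error structure, not predictions for any
physical device. With the default bands the simulated MVPA bouts sit
well above the 50% cut-off, so detection sensitivity is high (~98%)
despite the −16 bpm bias; real free-living MVPA clusters nearer the
threshold, where the same bias destroys sensitivity. The pipeline's
correctness claims are about the statistics, which are validated against
independent oracles and exact-arithmetic fixtures.

## Numerical choices and degenerate inputs

- ICC requires ≥ 3 epochs and nonzero total variance; mean difference
  and Bland–Altman require ≥ 2 pairs; deciles require ≥ 10. Strata below
  these minimums are reported as insufficient with the reason, never
  silently dropped.
- The ICC CI collapses to a point at ICC = 1 (zero residual variance);
  the Satterthwaite denominator guards against division by zero.
- Heart rates are validated to [0, 250] bpm at parse time; 250 is above
  the `220 − age` maximum for any adult and guards corrupt input. Ages
  are validated to [18, 120].
- Duplicate timestamps in a stream file are an error, not a
  deduplication opportunity — silent repair would mask device export
  bugs.
- CSV outputs round floats to fixed decimals (4 for statistics, 6 for
  p values) so that byte-identical reruns are well-defined.

## Problem sizes

The default scenario — 10 participants, ~4.5 h sessions, 30 follow-up
days — yields ~2400–2800 paired minutes and ~250–300 valid person-days;
the full simulate + analyse cycle takes a few seconds, and the test
suite under a minute. These sizes were chosen as the smallest at which
the stratified statistics are stable enough for 3-SE recovery tests.
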