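# Methods

## Dosing algorithms

All three bolus rules are pure functions of the meal's macronutrient
masses and the patient's insulin parameters.

* **ICR (500 rule).** ICR = 500/TDD grams of carbohydrate per insulin
  unit. A 31.77 U/day patient gets 15.74 g/U. The quotient is oriented
  so its units are g/U, matching how clinicians state the ratio ("1 unit
  per 15.74 g").
* **Fat-protein energy.** Atwater factors, 4 kcal/g protein and 9 kcal/g
  fat; carbohydrate energy never enters the FPU term, and fiber carries
  neither energy nor insulin.
* **FPU counting.** `pf_kcal / kcal_per_FPU`, with 200 kcal per unit in
  the modified algorithm and 100 kcal in the original Pankowska
  equation. The default *rounded* mode rounds half-up to a whole unit —
  the clinical counting convention, and the one that maps the shipped
  NPM (1.405 raw) and HPFM (1.8125 raw) fixtures to 1 and 2 FPU. A
  *fractional* mode keeps the exact quotient for sensitivity analyses.
  Half-up (not banker's) rounding is deliberate: an exactly-half unit
  should not silently round down to less insulin.
* **Dose-increment rounding** applies to the summed total only, half-up
  to the nearest pen increment; the decomposition (`carb_units`,
  `fpu_units`) is kept exact so `total_units` always equals their sum.
* No insulin-on-board, correction term or glycemic-index adjustment is
  modeled; the algorithms describe a preprandial bolus under controlled
  test-meal conditions.

## CGM outcome metrics

Inputs are discrete flash-monitor readings (mmol/L) on a nominal 15-min
grid over 0–300 min with a mandatory baseline reading G0 at t = 0.

* **Window means** use closed intervals, so a reading at a window edge
  (e.g. 120 min) contributes to both adjacent windows — matching the
  overlapping reporting windows (0–120, 0–240, 0–300, 120–240, 240–300).
* **Peak** is the maximum over post-baseline readings (0, 300]; ties
  resolve to the earliest time.
* **AUC** is trapezoidal. **iAUC** subtracts G0; the default *net*
  policy keeps sub-baseline area (a trace ending below baseline can have
  negative iAUC — the separate ΔLow statistic reports the nadir
  explicitly), while *positive_only* truncates sub-baseline segments at
  zero, splitting segments at linearly interpolated baseline crossings.
  The net policy satisfies the identity iAUC = AUC − G0·t exactly.
* **Time in ranges** is the fraction of readings — not interpolated
  duration — inside the closed interval [3.9, 10.0] mmol/L, strictly
  above 10.0, and strictly below 3.9, summing to 100 by construction.
  Discrete samples are the honest granularity of 15-min flash data.
* **Hypoglycemic episodes** are maximal runs of consecutive readings
  strictly below 3.9 mmol/L; a single reading qualifies (no duration
  criterion), and the onset is the first sub-threshold reading's time.
* **30-min excursions** require actual readings at every 30-min
  multiple; missing grid points fail loudly rather than interpolate.
* **MAGE** follows the classical turning-point procedure: collapse
  plateaus, list local extrema including both endpoints, take
  differences between consecutive extrema, keep those exceeding one
  sample SD (ddof = 1) of the full trace, and average the kept
  amplitudes in the direction (rising or falling) of the first one;
  0 when nothing qualifies. MAGE has no universally fixed definition;
  whether boundary half-swings count is the biggest interpretive choice
  here. We count them — a monotone rise from 6 to 12 mmol/L is a real
  excursion even though it contains no interior turning point — and the
  test suite pins the behavior with a brute-force oracle. MAGE is
  invariant to additive shifts and scales linearly with positive
  factors.

## Synthetic crossover generator

The simulator produces four-arm (2 meals × 2 algorithms) within-subject
crossover datasets for pipeline testing. It is phenomenological, not
mechanistic: each trace is a linear superposition of unimodal response
kernels

    r(t) = (t/t_peak)^k · exp(k·(1 − t/t_peak)),  r(0) = 0, r(t_peak) = 1,

one each for carbohydrate, protein/fat and insulin, plus AR(1) sensor
noise, evaluated on the 15-min grid and clipped below at a physiological
floor (default 2.2 mmol/L). An oral-minimal-model ODE would need
physiological parameters the use case does not supply; kernels with the
right timing statistics are sufficient for testing dosing → metrics →
analysis pipelines.

Defaults (all configurable):

| parameter | default | rationale |
| --- | --- | --- |
| carbohydrate kernel | peak 130 min, shape 5 | early meal rise, peak ~2 h |
| protein/fat kernel | peak 260 min, shape 12 | delayed, protracted rise in the 1.5–6 h window |
| insulin kernel | peak 250 min, shape 2.5 | cumulative glycemic *depression* of the bolus, which outlasts the plasma-insulin peak; a late-weighted kernel is what lets a larger dose suppress the late protein/fat rise more than the early carbohydrate rise |
| carb sensitivity | 0.160 mmol/L per g | fitted, see below |
| protein/fat sensitivity | 0.0167 mmol/L per kcal | fitted |
| insulin sensitivity | 1.86 mmol/L per U | fitted |
| baseline | N(6.5, 0.4) mmol/L, clipped to [3.9, 10] | fasting admission window |
| TDD | lognormal, mean 31.8 U, CV 0.29 | consistent with a mean ICR of 15.74 g/U |
| subject multipliers | lognormal, σ = 0.25 on each sensitivity | between-subject spread comparable to reported SEs |
| sensor noise | AR(1), ρ = 0.5, SD 0.35 mmol/L | smooth interstitial traces |

The three base sensitivities were fitted once by penalized least squares
of the noise-free superposition against the reference cohort statistics
shipped as calibration targets: the four arm means of 0–300 min glucose
(9.25, 6.96, 7.94, 7.34 mmol/L — each reproduced within 1 mmol/L), the
arm peak levels (11.87, 9.33, 10.01, 9.40 mmol/L), the peak-time
ordering (carbohydrate-counted high protein-fat meals peak late, ~4 h;
FPU-dosed ones peak early, ~2–2.5 h), and the constraint that the
noise-free carbohydrate-counting arms never go hypoglycemic. These
targets are not mutually consistent under any linear dose–response
model — the normal-protein arm pair implies an insulin effect several
times larger than the high protein-fat pair's — so the fit distributes
residuals; the shipped defaults keep every arm mean within 1 mmol/L.

Hypoglycemia handling: when a reading falls below 3.9 mmol/L the default
*rescue* mode superimposes a 15-g carbohydrate response from that
reading's time onward, once per below-threshold run (one juice per
event); *truncate* mode instead ends the trace at the first
sub-threshold reading, and *none* disables both.

What the generator does **not** emulate: gastric emptying and
absorption physiology, carbohydrate–fat interaction effects on
absorption rate, insulin-on-board from prior boluses, sensor drift,
dropout or compression artifacts, circadian insulin-sensitivity
variation, or any within-subject correlation structure beyond the
shared subject multipliers. Passing tests therefore demonstrate that
the pipeline computes its statistics correctly on data with realistic
timing and variance structure — not that the dosing algorithms would
produce these outcomes in patients. Simulated hypoglycemia frequencies
in particular run somewhat higher in the carbohydrate-counting arms
than feeding trials report, because the lognormal sensitivity
multipliers occasionally produce strongly insulin-sensitive subjects.

## Crossover analysis

The unit of inference is the within-subject FPU − CC difference for a
given meal type; subjects missing either arm are excluded and counted.
Mixed models are out of scope by design — the paired difference is what
the crossover supports directly.

* **Paired t**: one-sample t on the differences, two-sided p from the
  t distribution with n−1 df. Zero-variance differences return t = 0
  with p = NaN (all-zero) or ±inf with p = 0.
* **Wilcoxon signed-rank**: zeros dropped, midranks for ties. For n ≤ 15
  the two-sided p is exact, computed by dynamic programming over the
  2^n sign-assignment distribution of the positive-rank sum (midranks
  are doubled to integers); beyond 15, a normal approximation with
  continuity correction and the standard tie correction. The exact path
  is verified against full enumeration in the tests.
* **Hypoglycemia**: per-arm counts of subjects with ≥ 1 episode,
  percentages always printed with their denominator, and an exact
  discordant-pair binomial (McNemar) test between algorithms.
* No multiple-testing correction is applied; reports state the number
  of comparisons made so readers can apply their own.

## Numerical and I/O choices

* Times are integer-valued minutes relative to meal start throughout;
  only the FreeStyle-Libre adapter touches timestamps. Glucose is
  mmol/L end-to-end; mg/dL is converted at the boundary (÷ 18.016).
* Report files are deterministic byte-for-byte: fixed column order,
  two decimals for mmol/L quantities, one for percentages, sorted JSON
  keys. All randomness flows through a single integer seed recorded in
  the simulation manifest.
* Degenerate inputs fail loudly: empty windows, off-grid AUC end-times,
  traces without a t = 0 baseline, non-positive glucose, duplicate
  (subject, arm, time) rows and sub-2-reading tests all raise with a
  location-bearing message.

## Problem sizes

The test suite and the acceptance script simulate 30-subject four-arm
trials (120 traces of 21 readings) and run randomized-oracle sweeps of
100–150 cases per property; the full suite completes in a few seconds
on one core.

## Known limitations

* The dosing algorithms assume a single preprandial bolus under fasting
  test-meal conditions; they are not a general bolus calculator.
* MAGE on 21-point traces is coarse; with few readings a single noise
  spike can dominate the amplitude set.
* The simulator's linearity means doubling a meal doubles its glycemic
  excursion exactly — useful for testing, wrong physiologically at
  large loads.
* Calibration reproduces arm-level summary statistics, not individual
  trace morphology; do not use simulated traces to benchmark sensor
  algorithms.
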