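# Methods

This note documents the models, defaults and numerical choices behind
`rehabkit`, and what its synthetic-data validation does and does not show.

## Synthetic stream model

The generator emulates the wearable kit — two strap-on 9-axis IMUs for limb
exercises, a glove with one IMU and five flex sensors for hand exercises —
at the devices' nominal 30 Hz sampling rate.  A training bout is a lead-in
pause followed by `n_reps` repetitions separated by pauses.

* **Repetition profile.** A raised cosine,
  `s(t) = A/2 (1 − cos 2πt/T)`, `0 ≤ t < T`: a smooth out-and-back movement
  that starts and ends at baseline and has peak-to-trough span exactly `A`.
  It was chosen over a minimum-jerk polynomial because its amplitude and
  derivative are closed-form, which makes amplitude- and jerk-recovery
  checks analytic.
* **Units.** For limb exercises the primary signal is resultant
  acceleration in g riding on 1 g of gravity along the device z axis; the
  proximal device moves at half gain (the distal segment travels farther).
  For hand exercises the primary signal is the wrist pitch angle in
  degrees: the glove accelerometer is a unit gravity vector tilted by
  `s(t)`, and the five flex channels mirror the normalized profile mapped
  onto [0.1, 0.9] of their 0–1 range (no waveform model exists for the real
  glove, so the flex channels are deliberately simple).
* **Defaults.** `rep_duration = 3 s`, `pause_duration = 1 s` — a slow,
  deliberate pace typical of guided rehabilitation movements;
  `amplitude = 2 g` for limb exercises and 45° of wrist pitch for hand
  exercises; `noise_sd = 0`; `smoothness = 1`.
* **Tremor.** `smoothness < 1` adds two sinusoidal components with
  frequencies drawn uniformly from 4–8 Hz (the physiological tremor band),
  scaled by `0.15·A·(1 − smoothness)` and enveloped by the normalized
  profile so repetition boundaries stay clean.  This inflates JERK in a
  controllable way without materially changing AMP.
* **Determinism.** All randomness flows from one `numpy` generator seeded
  per call; equal parameters give bit-identical streams.
  `degrade_repetitions` rebuilds the stream from its stored parameters with
  the same seed, drawing tremor parameters and noise in a scale-independent
  order, so only the listed repetitions change and the noise realization is
  preserved exactly.

**What this does not emulate:** real limb kinematics (multi-joint coupling,
compensatory trunk motion), magnetometer disturbance, sensor drift, dropped
packets, or the actual waveforms of the standard training videos.  Passing
tests demonstrate that the pipeline recovers what the generator encodes;
they do not validate recognition accuracy on real patient movement.

## Preprocessing and segmentation

* **Sliding filter.** Centered moving average, default window 5 frames
  (~0.17 s at 30 Hz) — the minimal reading of "sliding filtering".  At the
  edges the window truncates to the available samples, so output length
  equals input length and constants are preserved.  With the 3 s default
  repetition, the window attenuates the profile peak by about 0.5%, which
  keeps filtered amplitude recovery within the 1% test tolerance.
* **Orientation rebasing (headless mode).** Each device's first filtered
  accelerometer and magnetometer vectors define a TRIAD frame (gravity up;
  the magnetic component orthogonal to gravity fixes heading); all vector
  channels are re-expressed in that frame.  Using both vectors pins all
  three rotational degrees of freedom, so a stream pre-rotated by *any*
  fixed rotation rebases to the identical result (verified to 1e-9) and all
  downstream features are placement-invariant.  The first filtered sample
  is used rather than an averaged rest pose, matching a device that zeroes
  itself at movement onset.  Degenerate initial vectors (free fall,
  magnetic field parallel to gravity) raise an error rather than guessing.
* **Segmentation.** No published rule exists for delimiting repetitions, so
  the package uses hysteresis thresholding of the filtered primary channel:
  a segment opens at baseline + 0.3 × range and closes below half that
  excursion, then extends outward until the signal rejoins the baseline
  (within 1% of range).  Baseline and range are the 1st/99th percentiles of
  the filtered signal rather than min/max, so single noise spikes cannot
  inflate the thresholds and a repetition sitting near the entry threshold
  is not lost to the peak sample of the largest one.  Segments shorter than
  0.5 s (15 frames) are discarded.  The rule is justified empirically:
  on noiseless synthetic streams it recovers the exact repetition count
  with boundaries within ±3 frames of ground truth, and the count is stable
  up to noise of 5% of amplitude.

## Features

AMP is `max(x) − min(x)` (the span of the movement — the only reading
consistent with "magnitude of the movement"); MEAN and RMS are the ordinary
arithmetic mean and root mean square.  JERK is

    J = [ (1/(N−1)) Σ ((x[i+1] − x[i]) · f_s)² ] / (f_s² · AMP²),

a mean squared first derivative normalized by sampling rate and amplitude:
dimensionless, scale-invariant (`J(kx) = J(x)`), zero for constants, lower
for smoother movement.  Numerically the division by AMP is applied inside
the square so near-constant signals cannot underflow the denominator.
Strength is the time-mean of the mean flex-channel deflection from the
first frame, clipped at zero; for exercises without the glove it is
reported as 0 with an availability flag instead of raising, so limb
pipelines need no special-casing.

Feature extraction operates on the *filtered* primary channel of each
detected segment — the same signal segmentation saw — which trades a
sub-percent amplitude bias for noise robustness; the reference template is
built through the identical path, so the bias cancels in similarity scores.

## Scoring

Per-feature similarity is `max(0, 1 − |f − ref| / |ref|)` clipped to [0, 1]
(an absolute scale is used when `ref = 0`).  The repetition score is the
weighted similarity over the mode's active features:

* easy: AMP alone (weight 1);
* moderate: AMP and RMS at (0.7, 0.3) — an interpolation between the two
  published modes, configurable per template;
* hard: all five features at (0.5, 0.2, 0.1, 0.1, 0.1) in
  (AMP, MEAN, RMS, JERK, Strength) order.  For exercises without the glove,
  Strength is undefined and the remaining weights renormalize to
  (0.5, 0.2, 0.1, 0.1)/0.9 — preferable to scoring a dead feature as zero,
  which would cap every limb repetition at 0.9.

Validity thresholds are 0.40/0.60/0.80 for easy/moderate/hard, *inclusive*
(a score exactly at threshold is valid).  Each valid action adds one game
point; the session score is 100 × valid / total repetitions.  The
same-difficulty weights are the default for every exercise since only one
exercise's modes are published; templates are plain data and fully
configurable.

Reference templates are derived by running the full pipeline on a
noise-free generated bout at the exercise's reference amplitude — the
package's stand-in for the standard training video's feature references.
Because template and session go through the same path, a perfect session
scores exactly 1 per feature.

## Prescription logic

Initial difficulty maps the enrollment Fugl-Meyer total (0–100) through
thirds of the scale: ≤33 easy, 34–66 moderate, ≥67 hard (no published cut
points exist; the bands are configurable).  Adaptation runs at most once
per calendar day: a session-score change of more than 5 points steps the
difficulty one level (up for improvement, down for decline), clamped to the
scale; changes of 5 points or less are ignored.  Repetition targets and
session length (default 30 min, twice daily) are manual prescription
fields, not automated.

## Trial statistics

* **Sample size.**
  `n = ⌈(z_{α/2} + z_β)² · 2σ² / (|μ₁ − μ₂| + δ)²⌉` with `δ` a fraction of
  σ.  With z = 1.96 and 0.84, μ₁ = 11.0, μ₂ = 10.0, σ = 5.5 and a 40%
  margin (δ = 2.2): n = ⌈46.32⌉ = 47; with 20% dropout, ⌈47/0.8⌉ = 59.
* **Confidence intervals** use the Student-t quantile with n−1 degrees of
  freedom — this reproduces the published limits from the published
  (n, mean, SD) triplets, where a normal quantile does not.  Computation is
  full precision; report output rounds to 2 decimals.
* **Two-sample tests** default to Welch's unequal-variance form (the safer
  choice when only "t test" is stated); the pooled form is available and
  agrees to 3 decimals on the trial's own summaries.  The p value is
  cross-checked in the tests against direct numerical integration of the
  hand-written t density.
* **Proportions** are compared with the Pearson chi-square statistic
  *without* continuity correction — the SAS default, and the form that
  reproduces the published adverse-event p value — alongside Fisher's exact
  test, which is the one to report when any expected cell is below 5.
* **Randomization** is stratified permuted blocks: within each stratum
  (study center), consecutive blocks of even length (default 4 — a set but
  unpublished value) contain each arm exactly half the time, shuffled by a
  seeded generator.  Any prefix is imbalanced by at most half a block;
  complete strata are exactly 1:1.
* **FMA model.** 50 items in {0, 1, 2}, partitioned 33 upper / 17 lower;
  subtotals are bounded by 66/34 and the total by 100 by construction, and
  item-level validation rejects anything outside the scale.

Patient-level clinical outcomes are out of scope: only quantities derivable
from summary statistics are recomputed, which is also why the two
experimental-arm CI limits that disagree with recomputation in the last
printed decimal (a consequence of rounding mean/SD before publication) are
checked at the recomputed value or at the limit that does reproduce.

## Problem sizes

The validation suite runs on bouts of 5 repetitions (≈630 frames, ~21 s of
signal) and randomization lists of 120 patients — the scale of one real
training session and of the full trial — so the entire suite and the
acceptance script complete in seconds while exercising every code path at
realistic size.
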