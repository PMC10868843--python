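# Methods

## Joint model and conventions

Quaternions are scalar-first (w, x, y, z), Hamilton convention, and encode
the rotation from the sensor/segment frame into the world frame. The package
never assumes a particular mounting frame; the static neutral-posture
calibration absorbs it. The double cover (q ≡ −q) is resolved by w ≥ 0 for
isolated quaternions and by sign continuity (flip any sample whose dot
product with its predecessor is negative) along streams.

Sensor-to-segment registration stores, per segment, the conjugate of the
mean static orientation over the calibration window (≥ 0.5 s). The mean is
the sign-aligned component-wise average, renormalized — a chordal
approximation to the Karcher mean that is accurate to second order in the
dispersion and exact in the limit of a perfectly still pose; for the
sub-degree dispersion of a usable static trial the approximation error is
negligible. A window in which either segment deviates more than 5° from its
mean is rejected as non-static.

The joint rotation is the change-relative-to-static composition
J(t) = C_thighᵀ C_shank with C_seg(t) = R_seg(t)·R_seg(static)ᵀ, decomposed
with an intrinsic Cardan XYZ sequence (flexion about X, adduction about Y,
internal rotation about Z — the biomechanics standard for joint angles).
Two properties are worth stating precisely:

* With the registration held fixed, J is exactly invariant to any rigid
  rotation of the world applied to both segments.
* If the calibration is *also* redone in the rotated world, J is conjugated
  by the world rotation: its rotation angle (hence any angle-magnitude ROM)
  is preserved, but the individual Cardan angles re-express in the new
  frame. This is the familiar heading-reference sensitivity of IMU joint
  angles; it is why all angle comparisons in this package are made against a
  reference channel calibrated in the same session.

Cardan decomposition is singular when the middle (adduction) angle reaches
±90°. Samples within 0.5° of the singularity are flagged, never clamped;
knee adduction never approaches this region in practice, so the flag is a
data-quality tripwire rather than a working code path.

## Pipeline parameters

| parameter | default | rationale |
|---|---|---|
| kinematic sample rate | 200 Hz | orientation stream rate |
| GRF sample rate | 1000 Hz | force-plate rate |
| low-pass filter | Butterworth, 2nd order, 6 Hz, zero-phase | standard for gait signals; forward–backward application avoids phase lag (and squares the magnitude response) |
| GRF event threshold | 20 N | common force-plate practice |
| event hysteresis | 50 ms | suppresses chatter at threshold |
| task-bound speed threshold | 5 °/s on the 6 Hz-filtered flexion channel | bounds squat / sit-to-stand excursions ≥ 20° |
| cycle plausibility | 0.5–10 s | rejects spurious segmentations |
| cross-correlation max lag | half the shorter curve | applied to all planes from the flexion-channel lag |
| normalization | cubic spline to 101 points, 0–100 % inclusive | |
| alpha / correction | 0.05, Bonferroni over 3 pairs (0.017) | |

Gait events are detected on the filtered force but each instant is then
refined to the nearest same-direction crossing of the raw channel. Zero-phase
smoothing stretches the loading edge, so the filtered crossing time otherwise
drifts by tens of milliseconds when the force amplitude changes; the raw
refinement makes event timing amplitude-invariant to within a millisecond.

Walking cycles span heel-strike to next ipsilateral heel-strike (full gait
cycle, configurable); stair cycles span successive contacts. Whether a study
normalizes walking to the full cycle or stance only is a convention choice;
full cycle is the default here.

RMSD and Pearson R are computed on mean-centered 101-point curves by
default: subtracting each trial's mean removes the constant offset that a
flexed calibration pose injects, which would otherwise dominate RMSD without
reflecting waveform fidelity. Raw-curve comparison is available
(`center=False`). ROM is max − min per cycle and is invariant to centering.
Correlation bands are half-open upward-inclusive intervals
([0, .60) poor, [.60, .75) moderate, [.75, .85) good, [.85, .95) very good,
[.95, 1] excellent); a value exactly 0.95 is "excellent", and negative R is
banded "poor" with a warning.

The repeated-measures ANOVA is the one-way within-subject F:
F = MS_method / MS_method×subject with df = (k−1, (k−1)(n−1)), complete
cases only, no sphericity correction (with k = 3 conditions the maximal
correction is mild, and plain F/p is what validation studies customarily
report). The suite cross-checks F and p against statsmodels' AnovaRM and
pingouin on toy tables, and its type-I-error rate is verified at the nominal
0.05 over 10,000 simulated null cohorts. Post-hoc paired t-tests report the
uncorrected p against the corrected threshold 0.05/3 ≈ 0.017 and t-based
95 % CIs with n−1 degrees of freedom; an identically-zero difference column
yields p = 1 with a point CI.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes — not
any particular hardware. Defaults describe a cohort of 21 participants
performing five tasks with five repetitions each; per-participant sagittal
ROM is drawn per task from (mean, SD) of 60.40 (8.77) for walking, 78.85
(11.73) squat, 77.42 (23.51) sit-to-stand, 88.56 (9.72) stair ascent, 88.90
(9.63) stair descent (truncated at 20°), with cycle durations of 1.1 / 3.0 /
2.5 / 1.4 / 1.4 s jittered ±10 % and body mass ~ N(93.89, 24) kg for GRF
scaling.

Flexion waveforms: walking is a periodic double bump (loading-response wave
plus swing peak, built from von Mises bumps); squat and sit-to-stand are
single raised-cosine excursions separated by 0.75 s rest; stair tasks are a
single large excursion with a saturating plateau. Each waveform is scaled so
the flexion ROM equals its target exactly; out-of-plane truth defaults to
8° (frontal) and 10° (transverse) ROM. The thigh's world motion is a smooth
rotation proportional to flexion (gain −0.35); joint angles depend only on
relative orientation, so this choice matters solely for how drift and
soft-tissue errors interact with absolute motion.

The corruption model composes, per method channel:

| source | r_IMU | m_IMU | mechanism |
|---|---|---|---|
| white orientation noise | 2.2° SD | 2.0° SD | per-sample random rotation, attenuated ×0.3 at rest |
| gyroscopic drift | 4.0 °/√s | 3.5 °/√s | random-walk rotation about a fixed random axis per segment |
| soft-tissue artifact | 8.0°, phase 50° | 7.5°, phase 50° | thigh-only oscillation about (roughly) the flexion axis tracking the flexion cycle with a phase lag, signed so peak flexion is underestimated |
| calibration-pose offset | 4.0° | 3.0° | the static recording is generated at a flexed knee, so registration biases subsequent flexion by a constant without touching ROM |
| crosstalk misalignment | 12° | 10° | fixed sensor-frame rotation applied to motion trials but not statics, so registration cannot cancel it |
| stair disturbance | ×3 on drift / soft-tissue / crosstalk | ×3 | instrumented-staircase electromagnetic interference |

These magnitudes are a documented stand-in chosen once so that the cohort
mean sagittal RMSD falls in the 2–8° range for the level tasks with stair
tasks larger — the ordering and scale reported by IMU validation studies —
and are not a claim about any specific sensor. The m_IMU channel represents
a vendor kinematic model only as a second, slightly smoother measurement
channel, and exports the sagittal plane only.

What the synthetic cohorts do **not** emulate: raw accelerometer/gyroscope
signals and the sensor-fusion step (the generator corrupts fused
orientations directly), magnetometer disturbance fields beyond generic drift
and the stair scale factor, marker-based kinematics of the reference channel
(the truth plays that role noise-free), inter-system clock offset (streams
share a timebase, so the cross-correlation alignment stage is exercised by
construction at lag ≈ 0 and separately unit-tested at known lags), and
heteroscedastic participant-specific soft tissue. Passing tests on these
cohorts therefore demonstrates the correctness of the computation chain and
the direction/scale behaviour of the error model — not hardware performance.

## Numerical choices and degenerate inputs

* Quaternion interpolation onto the common timebase is component-wise linear
  with renormalization — indistinguishable from slerp at 200 Hz sample
  spacing for human movement.
* Quaternion → matrix conversion requires unit norm within 1e-6; produced
  matrices are orthonormal within 1e-9. Zero-norm quaternions raise a
  dedicated degenerate-quaternion error.
* Cross-correlation ties break toward the smallest |lag|; zero-variance
  inputs are rejected; peak correlation below 0.5 warns.
* Cubic-spline resampling needs ≥ 4 samples; linear ramps reproduce exactly
  (splines are exact on polynomials up to cubic).
* Streams must overlap for at least half of the shorter stream; disjoint
  ranges are an error, as are non-monotone timestamps and missing CSV
  columns (named in the message).
* All randomness flows from one explicit integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical cohorts and
  output files.

## Known limitations

* The heading sensitivity above: Cardan angles are expressed relative to the
  calibration-session world frame; comparing channels calibrated in
  different magnetic environments would add a frontal/transverse bias this
  package does not model or correct.
* The soft-tissue model is a single phase-lagged oscillation on the thigh;
  real artifact is broadband, participant-specific, and affects optical
  markers too.
* Representative-cycle selection takes the middle repetition; no
  data-quality scoring of candidate cycles is implemented.
* The ANOVA assumes complete cases; participants missing a method are
  dropped from that task's ROM comparison rather than imputed.
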