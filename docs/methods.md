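# Methods

This note documents the models, numerical choices and limitations behind
`tugkit`, in the order the pipeline runs.

## Signal model and conventions

A recording is a strictly increasing time series of 3-axis specific force
(m/s², gravity included) and 3-axis angular velocity (rad/s) in the device
frame, nominally 100 Hz.  Because phone clocks jitter, the first step
interpolates linearly onto an exact uniform grid; linear interpolation is
the minimal-assumption choice and is exact for the band of interest at
100 Hz.

Body axes are ML (medial-lateral), AP (anterior-posterior, forward
positive) and CC (cranio-caudal, up positive).  The mounting enum maps
device axes onto body axes with a proper rotation (det = +1), so the same
matrix applies to accelerometer and gyroscope vectors and sample-wise
vector norms are preserved.  The default `portrait_back` mounting describes
a phone held vertically against the sacrum by a belt: device X → ML,
device Y → CC, device Z → −AP.  At rest the CC channel reads −g.

Gravity handling is mean subtraction, not tilt compensation: each analysis
segment is demeaned (or the whole recording, for the `remove_gravity`
flag).  This matches single-sensor trunk accelerometry practice and avoids
coupling displacement estimates to orientation-filter accuracy.  Trunk tilt
does leak gravity into the horizontal axes; during stance that leak is not
noise but signal, and the stance model below exploits it explicitly.

## Filtering

All channels get a fourth-order Butterworth low-pass at 20 Hz applied
forward–backward.  Two passes square the magnitude response (an effective
eighth order) and cancel the phase; users comparing against a single-pass
implementation will see slightly more attenuation near the cutoff.  Edge
transients are controlled with odd-reflection padding of three filter
orders; series must be longer than that padding.

## Orientation

A complementary quaternion filter fuses gyroscope integration with the
accelerometer gravity direction: each sample, the attitude is propagated by
the body rates and then rotated toward the measured "down" by a fraction
`gain` of the tilt error (default 0.01 per sample at 100 Hz; `gain → 0` is
pure gyro integration, `gain = 1` snaps to the accelerometer tilt solution).
Correction is suspended when the acceleration norm leaves 0.5 g–1.5 g, and
an all-zero accelerometer degrades to gyro-only integration with a warning.
The initial attitude comes from the mean accelerometer vector over the
first 0.5 s.  No magnetometer is fused: yaw is only used differentially
(a 180° turn over ~2 s), where gyro drift is negligible.  Euler angles use
the ZYX (yaw-pitch-roll) convention; at gimbal lock the roll axis absorbs
the indeterminacy.

## Segmentation

The reference analysis segmented recordings by hand from signal plots, so
every threshold here is a configurable engineering choice validated against
the synthetic generator, not a published constant:

* activity = centred moving RMS (0.25 s window) of the norm of the
  baseline-referenced acceleration, with baseline statistics from the final
  5 s of stance; threshold = baseline mean + 3 SD;
* a yaw-rate gate at 0.52 rad/s (≈ 30°/s) marks turning;
* supra-threshold runs shorter than 0.2 s are never onsets by themselves;
  runs separated by dips shorter than 0.4 s belong to one activity burst
  (rhythmic gait dips below threshold at oscillation zero crossings);
* burst edges are re-located with a short (0.05 s) RMS window, because the
  wide centred window smears activity outward by about half its width.

The bursts after the cue map, in order, onto walk-out, turn+sit, stand-up
and walk-back.  When stand-up and walk-back merge into one burst (no pause
after standing, t7 = t6), the burst is split at its interior activity
minimum.  Detected events must satisfy
t0 < t1 < t2 ≤ t3 < t4 < t5 < t6 ≤ t7 < t8 or a segmentation error carrying
the partial result is raised.  Manual events pass through the same
validation and feed the identical downstream pipeline.

On the default synthetic conditions (accelerometer noise SD 0.05 m/s²)
about 99% of events land within 0.2 s of ground truth; t1 is the hardest
(the reaction-delay window occasionally contains a sustained noise
excursion).

## Displacement reconstruction

**Gait and generic segments** use frequency-domain double integration:
remove the mean, FFT, divide by −(2πf)², zero DC and all bins below the
high-pass cutoff, inverse FFT.  Cutoffs sit below the band of interest:
0.3 Hz for walking (step oscillations ≥ ~0.8 Hz), 0.05 Hz for stance.
The mean — not a fitted line — is removed first: subtracting a fitted line
from a finite window is a non-periodic perturbation whose sawtooth spectrum
the 1/f² division amplifies catastrophically (a 10 mm sinusoid reconstructs
to ~69 mm if a line is removed, to 10.0 mm with mean removal).  A `linear`
detrend mode remains available for comparison.

**Stance** is modelled as a small-angle inverted pendulum of length
L = 0.53 × body height (the anthropometric COM height; the lumbar sensor
rides at COM level).  The horizontal sensor acceleration is then
`a = ẍ + ω₀²x` with `ω₀² = g/L` — the tangential term plus the gravity
component leaking into the tilted axis.  At sway frequencies the leak term
dominates (at 0.3 Hz plain double integration would overestimate the
excursion roughly twofold), so the pipeline inverts the full transfer.
A naive spectral division by (ω₀² − ω²) is ill-conditioned on a finite
window: free oscillations exactly at the pendulum resonance
(f₀ = √(g/L)/2π ≈ 0.52 Hz) produce no measured acceleration, and spectral
leakage excites that blind spot.  The inversion is therefore solved as a
time-domain ridge-regularized least squares over second differences,

    min‖ẍ + ω₀²x − a‖² + (αω₀²)²‖x‖²,   α = 0.05,

a banded sparse system with no periodicity assumption; the ridge resolves
the resonance nullspace toward the minimum-norm solution and a final
projection removes its coherent sin/cos remnant.  The first and last second
of the reconstruction are excluded from the quantile statistics.  Noise-free
recovery error on narrow-band synthetic sway is below ~5%; under sensor
noise the resonance band still amplifies noise and inflates small sway
amplitudes by roughly 10–40% — a known limitation shared with any
drift-controlled inversion of this transfer.

**Transitions** (sit-down, stand-up) are rest-to-rest movements, so the
vertical excursion Δh comes from time-domain cumulative-trapezoid double
integration with zero initial velocity of the mean-removed CC acceleration
(mean removal enforces zero net velocity change).  A periodic FFT inversion
is structurally unable to represent a net monotone drop inside a 1.5–4 s
segment (it attenuates Δh by ~π), which is why this stage deviates from the
spectral route.  Δh is capped at 0.3 × height; power is m·g·Δh/duration.

## Parameter statistics

The "90th-percentile excursion" of a displacement series is computed
two-sidedly as half the 5th-to-95th-percentile spread.  For symmetric
signals this equals the 90th percentile of the absolute deviation from the
median, and it is translation-invariant and scale-equivariant; for a
sinusoid of amplitude A it equals A·sin(0.45π) ≈ 0.988 A.  Walking ranges
are reported peak-to-peak-like as twice the excursion, averaged over the
out and back walks.  Jerk is the central finite difference of the
low-pass-filtered acceleration magnitude (orientation-independent; a
per-axis mode exists), and its max − min within the gesture is reported.

## Synthetic generator

The generator builds every component analytically so ground truth is exact
and independent of the analysis code:

* **Stance sway**: a sum of six sinusoids drawn from 0.6–1.5 × the centre
  frequency (default 0.3 Hz) with random amplitudes and phases — or a
  single pure tone for closed-form tests — rescaled so the realized
  detrended stance excursion equals the profile amplitude exactly.  Sensor
  acceleration includes the pendulum gravity-leak term ω₀²x.
* **Walking**: a raised-cosine 3 m translation profile on AP (sharp onset
  and offset accelerations, as real gait initiation shows), CC oscillation
  at the step frequency and ML at half of it, with 0.3 s onset/offset
  envelopes.
* **Turn + sit / stand**: a raised-cosine yaw-rate pulse integrating to
  180°; cycloidal vertical transitions (zero velocity and acceleration at
  both ends, bounded jerk); a one-cycle 3 Hz acceleration bump at seat
  contact / seat-off sized so the clean jerk range matches the profile's
  target; a small 1.5 Hz postural-adjustment wobble spanning each
  transition.
* Gravity on CC, rotation into the requested device mounting, then white
  Gaussian sensor noise (accelerometer SD 0.05 m/s², gyro 0.01 rad/s by
  default).

True parameters come from the profile and the clean signals: stance
excursions are exact by construction; gait ranges are quantile ranges of
the true COM trajectory (equal to 2·0.988·amplitude in pure-tone,
no-envelope mode); powers are m·g·Δh/duration with the profile's Δh; jerk
ranges are measured on the clean acceleration magnitude; times follow from
the event grid.

The healthy and stroke presets are loosely anchored to the magnitudes
reported for non-stroke and chronic-stroke groups (e.g. walking ML range
~56 vs ~74 mm, reaction time ~0.77 vs ~1.15 s, total time ~11 vs ~16 s),
with the stroke preset wider in ML, flatter in CC, slower and weaker in the
transitions.  `simulate_cohort` jitters each profile field per subject with
a multiplicative CV (default 0.25, consistent with the reported
interquartile spreads), assigns mRS and FACHS labels from within-group
severity quartiles, and runs the full pipeline per subject with automatic
segmentation; if detection fails for an extreme profile the subject is
re-processed with the reference events and flagged in `events_source`,
mirroring manual re-annotation.

What the generator does **not** emulate: step-to-step variability and
asymmetry, stride-level events, soft-tissue and belt artefacts, gyroscope
bias drift, turning strategies other than a smooth 180° yaw ramp, and any
coupling between sway and gait amplitudes.  Passing the recovery suite
therefore demonstrates correctness of the signal processing under the
stated morphology, not clinical validity on real recordings.

## Statistics layer

Two-group comparisons gate on Shapiro-Wilk normality (α = 0.05 per group):
both normal → pooled-variance t (df = n₁+n₂−2; the published tables use
pooled df); otherwise Mann-Whitney U with the plain normal approximation
Z = (U − n₁n₂/2)/√(n₁n₂(n₁+n₂+1)/12), no tie and no continuity correction.
The plain form is a deliberate compatibility choice: it reproduces the
published effect sizes exactly (U = 549 with n = 36/33 → r = 0.065);
tie-corrected or continuity-corrected variants do not.  Both corrections
are available as switches.  The approximation is mildly anticonservative at
n = 30 per group (empirical size ≈ 0.066 on the rank branch, ≈ 0.051
aggregate over the normality gate).

Effect sizes: r = |Z|/√N from U, r = √(t²/(t²+df)) from t, labelled small /
medium / large at 0.12 / 0.20 / 0.32.  Correlations are Pearson when both
marginals pass normality, else Spearman; magnitude labels use contiguous
bands (< 0.1 negligible, 0.1–0.4 small, 0.4–0.7 medium, ≥ 0.7 large — the
source bands leave gaps at 0.3–0.4 and 0.6–0.7, which are closed at the
lower category boundary).  No multiple-testing adjustment is applied
anywhere, matching the analysis plan being reproduced.  Sample size for two
means uses the z-formula n = ⌈2σ²(z₁₋α/₂+z₁₋β)²/δ²⌉; the study-design
inputs (α = β = 0.05, σ = 10.11 s, δ = 9.57 s) give 29.005 → 30 per group.

One reproduction caveat: the published sit-to-stand power row prints
r = 0.147 for t = 1.212 (df 67); the conversion of either the printed or
the summary-statistics-recomputed t yields 0.1465, which rounds to 0.146.
The package reports the recomputed value.

## Problem sizes

The validation suite runs 100 seeded noisy recordings for event-detection
recovery, 100 repetitions of 30+30-subject cohorts for the directionality
and power of the group contrast, and 6000 null draws for the type-I
calibration (reported against the binomial 95% band of a 2000-draw design);
these sizes put Monte-Carlo standard errors comfortably below the margins
being asserted while keeping a full run in the low minutes on one CPU.

## Known limitations

* Absolute stance displacements are noise-inflated near the pendulum
  resonance (see above); between-group contrasts are affected equally in
  both groups.
* Transition power uses gravitational work only; kinetic-energy and
  horizontal-work terms are deliberately omitted, so absolute watt values
  are a lower bound tied to this definition.
* The segmentation thresholds were designed for the standardized protocol's
  morphology (quiet baseline, distinct activity bursts); free-living data
  would need different logic.
* Yaw is gyro-only; prolonged recordings would accumulate heading drift.
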