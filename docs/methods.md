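# Methods

This note documents the models behind `gazekit`, the assumptions baked into
each stage, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate about real recordings.

## Coordinate conventions

All rotation series are horizontal angles in signed degrees: negative =
left of body center, 0 = center, positive = right. Gaze-in-body is defined
sample-wise as eye-in-head + head-in-body. Time is in seconds on the eye
tracker's clock (the reference clock); the common analysis timeline is
uniform 30 Hz. Missing data (tracker dropouts, looks outside the scene
camera's field of view) are NaN and are excluded from every statistic.

## Synchronization (`io_sync`)

Each stream records on its own clock with unknown offset and drift. From
≥2 synchronization events observed both in the reference stream and in the
target stream (session start and end), an affine map
`t_ref = offset + scale · t_stream` is estimated — exactly interpolating
two events, least-squares for more. GPS timestamps are absolute UTC (as in
GPX files), so its sync events are POSIX seconds; the least-squares is
computed about the centroid so the huge offset costs no precision.

Resampling is linear interpolation for every stream: upsampling the 1 Hz
GPS and decimating the 400 Hz head series alike. No anti-alias low-pass is
applied before decimation; head movements have negligible power near
15 Hz, and plain interpolation is the minimal, analytically testable
choice. Dropout gaps are never bridged: timeline samples falling inside a
gap longer than `max_gap_s` (default 0.5 s) *and* longer than 1.5× the
stream's own nominal interval stay missing. The second condition keeps the
absolute threshold from blanking an entire 1 Hz stream whose normal
spacing already exceeds it.

## Pixels to degrees (`camera`)

The scene camera is modelled as an equidistant fisheye: the ideal
projection is r_px = f·θ with f = image_width / FOV_rad, which makes
degrees linear in pixel displacement from the principal point
(degrees = Δx · FOV/width, FOV = 111°). Lens distortion acts on the field
angle, θ_d = θ(1 + k₁θ² + k₂θ⁴); undistortion inverts this polynomial by
Newton iteration to 1e-12 rad (the tolerance is set so that the pixel
round trip closes to better than 1e-6 px at the image edge; convergence is
quadratic, so the tight tolerance costs about one extra iteration).
Non-converged points are flagged missing rather than raised. Calibration
error is the mean 2-D angular distance between validation targets and
estimated gaze after undistortion; a mean error above 5° (strict) excludes
the session.

The generator and the pipeline deliberately share this one parametric
family: the generator renders degrees to pixels through the *forward*
distortion, the pipeline inverts it, and round-trip tests close the loop.
Consequently the tests verify the inversion machinery, not the adequacy of
the equidistant-polynomial family for any particular physical lens —
coefficients for real cameras must come from an external intrinsic
calibration.

## Gaze-shift peaks (`kinematics`)

Peaks are strict local extrema of gaze-in-body (plateaus take the center
sample), recorded only when eye and head are rotated in the same nonzero
direction *at the peak sample*, with a minimum separation of 10 frames
(333 ms) resolved greedily in favor of the larger eccentricity.
Eccentricity is |gaze| at the peak relative to body center, not
shift-from-previous-fixation. Contributions are binned in eight half-open
10° bins [10,20), …, [80,∞), labelled by lower bound; peaks under 10° are
excluded. Empty bins are reported absent, never zero. An optional
`min_prominence` threshold exists but defaults to 0 (off).

Tie-breaks that the definition leaves open and that are fixed here: the
separation conflict keeps the larger peak; the same-direction test is
evaluated only at the peak sample; spread uses the n−1 sample SD.

## Locomotion (`locomotion`)

Geographic coordinates are projected by a local equirectangular tangent
plane about the track centroid (x = R·cos φ₀·Δλ, y = R·Δφ); versus
great-circle distances the error is far below 0.1% at pedestrian extents,
and tracks wider than 10 km are rejected. Path length is the segment sum
on the 30 Hz aligned track; because interpolation is linear, upsampling
adds no length by itself, but positional noise does — an optional moving
average (`smooth_window_s`) is available and off by default. Mean speed is
path length / task time by definition (not the mean of instantaneous
speeds, which differs under missing data); speed SD is the sample SD of
the per-frame instantaneous profile; the straightness ratio requires ≥1 m
net displacement and is undefined (error) for closed loops.

## Group statistics (`report`)

The outlier screen flags values beyond k = 3 SD of the within-condition
mean, computed leave-one-out so a single extreme value cannot mask itself
(with an inclusive SD a lone outlier among n ≤ 10 values can never reach
3 SD). Paired comparisons are two-sided paired t-tests with the paired
effect-size convention d = mean(diff)/SD(diff) ≡ t/√n. The task × effector
and task × eccentricity analyses are linear mixed models with participant
random intercepts, fit by REML (statsmodels MixedLM) with sum-to-zero
contrasts so each term is a Type-III-style main effect. Per-term F
statistics are Wald chi-square / df with a conservative denominator df of
n_obs − n_fixed; no Satterthwaite approximation is attempted. A singular
fit falls back, with a warning, to a repeated-measures ANOVA on
participant-cell means restricted to complete cells. Eccentricity bins
with no observations in one task make the interaction inestimable and are
dropped from the model with a warning. Holm–Bonferroni is implemented as
the step-down procedure with max-accumulated adjusted p-values; α = 0.05,
all tests two-sided.

## The synthetic-session generator (`synthetic`)

The generator emulates the study conditions of a two-task outdoor
protocol so that ingest, undistortion, composition, peak detection, and
locomotion can each be validated against known truth.

**Gaze model.** Gaze targets are zero-mean Gaussian with SD equal to the
task's spread target — walking 19.5°, searching 28.5° (the densities of
such data are unimodal and roughly symmetric about center, so a Gaussian
is the minimal choice). Shift onsets have a refractory dwell (default
1 s) plus an exponential tail, overall rate `shift_rate` = 0.5 shifts/s.
The empirical shift rate of this kind of recording is not established;
0.5/s is an assumption, configurable, and the measures are insensitive to
it except through per-bin peak counts. A target of eccentricity A splits
into head = A·f(A) and eye = A − head, where f is the monotone
head-recruitment policy; the eye is clipped at ±55° with the residual
reassigned to the head (shifts beyond the oculomotor range require the
head). The eye jumps to its component at onset (saccadic); the head
approaches its own with a first-order lag, time constant τ = 0.15 s, so
gaze settles onto the target as the head arrives. Default policies are
linear in amplitude: walking f(A) = 0.40 + 0.0035·A, searching
f(A) = 0.50 + 0.0030·A, chosen to reproduce the qualitative regime —
head contribution higher when searching at every eccentricity, rising
with eccentricity, and spread increases from walking to searching carried
mainly by the head with a modest eye increase. Measurement noise is
additive Gaussian (SD 1°) per sample on eye and head independently.

**Known generator biases.** Detected-peak contributions sit ~1–3
percentage points below f at the peak's eccentricity: noise makes the
recorded peak sample occasionally land before the head has fully settled,
and peak selection conditions on positive noise, which splits between eye
and head. Recovery tests therefore compare bin means against the policy
evaluated at the recovered eccentricities, with a 5-point tolerance.
Gaze-spread recovery runs ~4% below target for the same lag reason.

**Locomotion model.** Position advances along task waypoint polylines at
per-second speeds ~N(mean, SD) truncated at 0 — walking: the study route's
three legs (26 m E, 150 m N, 135 m E; 311 m), 1.17 ± 0.15 m/s; searching:
a circuitous ten-waypoint courtyard loop (~380 m traveled, net ~114 m),
0.75 ± 0.35 m/s moving speed with uniform 2–10 s dwells at each waypoint
(target retrieval), which yields the observed slow overall speed and high
speed SD without further assumptions. GPS error is a slowly drifting
AR(1) positional bias per axis (SD 0.5 m, lag-1 correlation 0.999 at
1 Hz, i.e. a drift time scale of ~15 min): smoothed consumer-watch output
shows exactly this low-frequency wander rather than white jitter, and
white jitter would spuriously inflate segment-sum path lengths.

**Rendering.** Streams are written in their own clocks,
t_stream = (t_true + offset)(1 + drift) — defaults: head +13.7 s with
2e-5 drift, GPS −4.2 s with 1e-5 drift on an absolute UTC base — with
sync events at session start/end. Eye angles pass through the forward
fisheye distortion; samples beyond the 55.5° half-FOV are written as
empty cells (missing). Head is resampled to 400 Hz, GPS written as GPX
1.1. Identical config + seed reproduces the bundle byte-for-byte.

**Cohorts.** `cohort_configs` adds participant-level random effects shared
across tasks — multiplicative gaze-spread factor (SD 0.15), additive
recruitment-baseline shift (SD 0.05), multiplicative speed factor
(SD 0.08), ±3 m waypoint jitter on interior waypoints, calibration error
uniform on 1.7–4.6° — so that random-intercept models are well-posed and
between-participant variability is on the order real cohorts show.

**What passing tests do not show.** The generator's eye and head
components are deterministically coupled to the gaze target, so eye and
head spreads are nearly perfectly correlated across time, unlike real
recordings where they partially decorrelate; compensatory (vestibulo-
ocular) eye movements during locomotion, vertical gaze, torsion, body/
trunk rotation, saccade kinematics, and realistic dropout patterns are
absent. Passing recovery tests validates the pipeline's arithmetic and
synchronization on signals with the right first-order structure — not the
behavioral realism of any conclusion drawn from real data.

## Problem sizes

Unit and property tests run on constructed series and 30 s random
signals; peak-detection oracle equivalence uses 200 random 30 s series.
End-to-end recovery uses 20 rendered sessions per task regime at full
session lengths (270 s walking, 730 s searching). Type-I-error
calibration of the paired t-test uses 2000 vectorized null replicates at
n = 20; mixed-model power and level checks use 10–40 replicates at the
study's n = 28. The cohort analysis drivers default to 28 participants ×
2 tasks.

## Known limitations

* Mixed-model p-values use conservative denominator df, so they are
  slightly conservative relative to Satterthwaite-corrected values.
* The head-contribution statistic is evaluated at the peak sample only;
  alternative definitions (e.g. shift-onset-to-peak amplitude) would give
  different values and are out of scope.
* The equidistant-fisheye family is assumed, not estimated; real lenses
  need external intrinsic calibration.
* Whether distances should be computed on raw 1 Hz or upsampled 30 Hz GPS
  is ambiguous in mobile-tracking practice; both are supported, 30 Hz is
  the default, and with linear interpolation the two agree exactly in the
  absence of missing data.
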