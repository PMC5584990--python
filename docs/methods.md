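# Methods

This note documents the models, numerical choices and known limitations of
`magtrack`.  Notation: θ is the magnet (≈ eye) angle in degrees, m₁/m₂ the
two sensor channel voltages in mV, e(t) eye position in degrees, k the
calibration factor in °/mV.

## Sensor model

Each AMR channel is a Wheatstone bridge whose differential voltage is
proportional to sin(2θ_field), where θ_field is the in-plane angle of the
external magnetic field; the two bridges are rotated 45° relative to each
other.  The forward model is

    V_c(θ) = A · sin(2(θ − φ_c)) + b_c,   φ = (0°, 45°),

with A the effective amplitude at the current geometry.  The response is
180°-periodic, so the usable range is one half-turn; during normal mouse
eye movements (±10–20°) at least one channel operates near a zero crossing,
its most linear and sensitive region.

**Sensitivity estimator.** Sensitivity is the mean |dV/dθ| within ±22.5° of
each zero crossing of a channel's output, averaged over crossings.  For an
ideal channel this has the closed form A·√2/45 mV/°, which converts between
amplitude and mean sensitivity.  The local slope uses centered finite
differences on the sweep grid (sweeps are dense and clean in simulation); a
least-squares slope over a configurable ±window is available for noisy
sweeps.  A channel with no crossing in the sweep reports NaN ("not
estimable") rather than raising, since a constant channel is a legitimate
degenerate input.

**Geometry attenuation.** The amplitude at vertical magnet-sensor distance
δ_v follows a monotone piecewise-cubic (PCHIP) curve through the bench
anchors 224.7/127.0/28.1 mV/° at 0/3/5 mm (expressed as amplitudes via the
closed form), held constant beyond 5 mm — the anchors are point
measurements, and PCHIP is the minimal monotone interpolant.  Horizontal
offset and lever arm act through a point-dipole model: the attenuation is
the mean field magnitude at the sensor over a ±22.5° sweep, relative to the
on-axis magnitude at the same δ_v, clipped at 1 (a stronger-than-on-axis
field cannot exceed the saturated bridge response).  This factor is 1 on
axis, monotone non-increasing in offset at zero lever arm, and ≈0.90 at the
1.5 mm offset corresponding to the mouse eye radius.  An earlier candidate —
the mean |d(field angle)/dθ| of the dipole — is kept as a diagnostic but is
*not* monotone in offset (the field direction swings faster near the dipole
equator) and is not used for attenuation.  Magnet tilt rotates the dipole
moment out of plane; it leaves the field-angle sweep on axis unchanged, so
a 45° tilt changes estimated sensitivity only negligibly, matching the
bench observation.  The dipole is a point approximation: it reproduces the
qualitative offset/tilt behavior but not finite-magnet field shapes.

The true calibration factor of a synthetic session is defined as the
reciprocal of the channel-1 slope at its zero crossing, k = 90/(πA) °/mV,
which is what both calibration methods estimate in the small-angle regime.

## Dual-angle video-oculography

With cameras separated by α = 40° and equidistant from the eye, the signed
horizontal pupil-CR distances obey Δ₁ = R_p sin(θ₁), Δ₂ = R_p sin(θ₂),
θ₁ + θ₂ = α.  The implementation inverts these as
θ₂ = atan2(Δ₂ sin α, Δ₁ + Δ₂ cos α) rather than the literal quotient
atan(sin α/(Δ₁/Δ₂ + cos α)): the two are algebraically equal for Δ₂ > 0,
but the atan2 form is well-defined at Δ₂ = 0 and continuous for signed
deltas.  The inversion is homogeneous of degree zero in (Δ₁, Δ₂) — the
formal statement that R_p (and any overall image scale) cancels.  Reported
eye position uses a symmetric-zero convention, eye = θ₂ − α/2, so 0° is the
bisector of the camera axes (the rig is aligned with the pupil roughly
centered between the CRs); which camera is nasal is a per-eye config flag,
since rig placement differs between eyes.

Only the horizontal (nasal-temporal) axis is modeled; vertical and
torsional components, and translation estimation, are out of scope (CR
subtraction already removes translation).

## Image processing

CR localization thresholds bright pixels (default 180 of 255), votes the
mask boundary into a circular Hough accumulator over radii 2–8 px, and
refines each peak to the intensity centroid of its blob (subpixel).  The
reference CR is the candidate nearest the image center, where the rig is
aligned to place it; the opposite camera's LED produces a displaced
distractor that is thereby ignored.  Masking replaces each CR disc (Hough
radius × 1.5 + 2 px) with the median of a 3 px annulus so specular
highlights cannot masquerade as pupil edges.

The Starburst pupil detector casts 36 rays from a seed point, takes the
strongest dark→light gradient along each ray (parabolic subpixel refinement
of the gradient peak), re-seeds at the candidate centroid until the seed
moves < 0.5 px (≤ 10 iterations), then fits an ellipse by RANSAC
(min 5 samples, 1 px residual threshold, 100 trials, fixed seed for
reproducibility) followed by a least-squares refit on the inliers.  Fewer
than 8 edge points or no consensus yields a flagged, non-converged fit.
Ray count, thresholds, radii and the mask safety factor are exposed as
parameters; the defaults were chosen for the synthetic renders.

Sync flashes are detected in the per-frame mean intensity at median +
6·MAD, with consecutive supra-threshold frames merged (a 30 ms flash spans
at most 2 frames at 30 frames/s; the onset is the first such frame, and
sub-frame timing is recovered by the alignment regression).

## Signal conditioning and alignment

* **Low-pass**: order-4 Butterworth applied forward-backward (zero phase).
  Because two passes square the magnitude response, the single-pass design
  cutoff is solved numerically (on the measured digital response, which
  also absorbs bilinear warping) so the cascade is −3 dB at the nominal
  cutoff, 100 Hz by default.
* **Differentiation**: per-sample least-squares slope in a centered window
  of the odd sample count nearest 50 ms (Savitzky-Golay, polyorder 1,
  derivative 1), with shrunken boundary-clipped windows at the edges.
  Exact on ramps; attenuates a sinusoid of frequency f by
  3(sin x − x cos x)/x³ with x = πfT — 0.25 % at 1 Hz, 10 % at 5 Hz for
  T = 51 ms.  A slope *fit* (not an endpoint difference) is used because it
  is exact on linear signals and robust to sample noise.
* **Desaccading**: samples with |velocity| above threshold (50 °/s for
  video-derived eye velocity, 5 mV/ms for sensor velocity) are excluded,
  dilated by a 50 ms pad on each side (transients have sub-threshold
  shoulders; the pad is a default, not a measured constant).  Masks from
  the two streams are OR-ed: a segment removed in either recording is
  removed from both.
* **Alignment**: flash frame-times (camera clock) are paired with TTL
  times (sensor clock) by nearest neighbor and regressed linearly, giving
  offset and drift; the video timeline is re-expressed in sensor time and
  the eye trace linearly interpolated to sensor samples.  A strictly
  periodic sync train makes the offset ambiguous modulo whole periods; the
  implementation assumes the camera stream starts after acquisition with a
  latency below one sync period (offset in [0, period)), which is how such
  rigs are started in practice.  Matching tolerates isolated missed
  detections (half-period slack, coarse offset from the first matched
  pair).  NaN gaps in the video trace are bridged by interpolation but
  stay excluded.

## Calibration

Position methods regress the aligned, desaccaded video eye position on the
sensor voltages.  One-channel fits each channel by OLS and selects the
channel with the larger |r| (absolute value, because implant polarity can
invert the sign; the slope of the selected channel is k).  Two-channel and
quadratic models use ridge regression on standardized regressors with a
25-point log-spaced penalty grid over [1e-6, 1e3]; the penalty minimizing
held-out squared error under 10-fold cross-validation is selected and the
model refit on all data.  Folds are *contiguous time blocks*, not random
samples — interleaved folds leak autocorrelated neighbors into the held-out
set and would select vanishing penalties.  Coefficients are reported on the
original mV scale.

The velocity method first upsamples the video eye position (linear, on its
own clock) to the sensor rate, so the 50 ms differentiation window has the
same frequency response on both streams and its attenuation cancels in the
amplitude ratio; both velocity traces are desaccaded, fitted with sines at
the known stimulus frequency via the linear sin/cos + DC basis (convex and
exact at a known, experimenter-controlled frequency), and
k = A_vid/A_mag using the channel with the higher sine-fit r².  Only
amplitudes enter, so a pure time shift between streams is irrelevant and no
flash alignment is needed.

On default synthetic sessions (60 s, 1 Hz, ±10 °/s, saccades at 0.2 Hz of
5 ± 2°, 0.02° fixation jitter, 2 mV sensor noise, 0.3 px landmark noise)
both methods recover k within a few percent and agree within ~1 %.  Two
small systematic effects are inherent to the measurement design, not bugs:
linear interpolation of 30 frames/s video attenuates a 1 Hz component by
~0.4 % (chord-vs-arc), and saccadic offsets place part of the trace on the
compressive flank of sin(2θ), biasing the position-method slope slightly
relative to the zero-crossing definition of k_true.

## Oculomotor metrics

Gain is the sine-fit amplitude of desaccaded eye velocity divided by the
stimulus amplitude — the nominal peak velocity (10 °/s) by default, or a
fitted amplitude when both traces pass through the same differentiation
window so its attenuation cancels (the recommended mode at ≥ 2 Hz, where
the 50 ms window attenuation exceeds the reporting precision).  Phase is
eye minus stimulus phase minus 180°, wrapped to (−180, 180]: 0° means
perfectly compensatory and positive means lead.  This zero convention is a
documented package choice.

Spatial resolution scans disjoint 2 s windows, keeps those whose
sliding-window velocity stays below 0.5 °/s ("relatively stationary" made
concrete), ranks them by velocity range and averages the mean-removed
position SD of the three quietest.

The motion index subtracts the pixel-wise mean background, takes the mean
absolute frame-to-frame difference, smooths with a centered 2 s moving
average (edge-renormalized), and labels the upper/lower tertiles of the
smoothed values Active/Still with stable-rank tie-breaking, so label counts
differ from n/3 by at most 1.  Background subtraction makes the index
invariant to global brightness offsets.

Binocular statistics use a common rightward-positive convention
(divergence = right − left); per-eye position SD and mean |velocity| are
averaged across the two eyes before reporting, and statistics are split by
Active/Still labels when provided.  The eye-head relation is an OLS slope
and Pearson r of desaccaded eye velocity on head yaw velocity.

## Synthetic sessions: what they emulate, and what they do not

The generator produces sinusoidal stimuli (0.2–5 Hz, ±10 °/s), an eye
response with specified gain/phase plus Poisson-timed saccades (20 ms
linear ramps with a re-centering bias beyond ±5° so the eye stays in range)
and white fixation jitter, sensor voltages through the forward model with
white Gaussian noise (2 mV SD, chosen so the voltage-referred noise floor
is ~0.016° at the 3 mm in-vivo-like sensitivity), 30 frames/s dual-camera
landmarks with Gaussian pixel noise and a 0.4 s camera latency, rendered
frames (soft-edged dark pupil ellipse, saturating specular CRs, distractor
CR at a fixed offset), 1 Hz/30 ms LED flashes in both TTL and frame
brightness, and overhead blob videos following a stepped activity schedule.
Everything is deterministic under a fixed seed (sub-seeds via
`SeedSequence.spawn`).

Not emulated: photorealistic eyes and eyelid occlusion, pupil-diameter
dynamics, torsional/vertical components, sensor drift and 1/f noise,
bilateral crosstalk, head-motion artifacts in the sensor.  Passing tests
therefore demonstrate the correctness of the *computational chain* under
the stated statistical assumptions, not performance on real video or real
implants.

## Problem sizes and defaults

Test and acceptance runs use 20–60 s sessions at 1 kHz sensor rate
(sensor rate is a config default; the video rate is fixed at 30 frames/s),
11-angle rendered sweeps at 640×480, and 60 s overhead videos at 64×64 —
sizes chosen so the full suite and the acceptance script each run in well
under a minute on a laptop-class core while leaving estimator variances far
below the tolerances being checked.

## Known limitations

* The dipole attenuation model is qualitative; anchors beyond 5 mm are
  extrapolated as constant.
* The Hough radius range and brightness threshold assume compact,
  near-saturating CRs; large or dim reflections need retuned parameters.
* Alignment assumes camera latency below one sync period (1 s at default
  settings); longer latencies alias to the wrong period.
* Ridge cross-validation assumes the calibration session is long enough
  for 10 contiguous blocks (> 100 included samples are required).
* The spatial-resolution stationarity criterion (0.5 °/s) is a convention;
  traces dominated by slow drift yield no usable epochs by design.
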