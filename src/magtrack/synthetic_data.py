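"""Ground-truth oculomotor session generator.

Synthesizes every observable stream the pipeline consumes, from a known
ground truth, so that calibration and analysis can be validated end to end:

* sinusoidal vestibular/visual stimulus (0.2-5 Hz, +/-10 deg/s peak
  velocity by default);
* an eye trace responding with specified gain and phase, plus Poisson-timed
  saccades (20 ms linear ramps) and white fixation jitter;
* two-channel AMR sensor voltages via the sensor forward model, with a
  1 Hz TTL sync-pulse train;
* dual-camera pupil/CR pixel landmarks at 30 frames/s (with camera-clock
  latency and drift relative to the acquisition clock), plus 30 ms LED sync
  flashes at 1 Hz embedded in the per-frame brightness;
* rendered grayscale eye images (dark pupil ellipse, bright reference CR at
  the image center, and a displaced distractor CR from the opposite
  camera's LED);
* overhead-video frames of a moving blob following a stepped activity
  schedule, for motion-index validation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import EyeTrace, SensorTrace, StimulusTrace
from .sensor_model import (
    AMRSensorSpec,
    MagnetGeometry,
    simulate_sensor_trace,
    small_angle_sensitivity,
)
from .video_geometry import CameraRig, PupilFrameSeries, forward_deltas

__all__ = [
    "EyeKinematicsSpec",
    "EyeImageSpec",
    "SessionBundle",
    "DEFAULT_FREQUENCIES_HZ",
    "generate_stimulus",
    "generate_eye_trace",
    "project_to_cameras",
    "render_eye_frames",
    "generate_overhead_motion",
    "generate_session",
]

#: Stimulus frequencies used throughout (Hz).
DEFAULT_FREQUENCIES_HZ = (0.2, 0.5, 1.0, 2.0, 5.0)


@dataclass
class EyeKinematicsSpec:
    """Parameters of the simulated oculomotor response.

    ``response_gain``/``response_phase_deg`` describe the slow-phase
    response relative to an ideal compensatory one (gain 1, phase 0 means
    the eye exactly counters the stimulus).  Saccades arrive as a Poisson
    process; amplitudes are Gaussian with a re-centering sign bias so the
    eye stays within its physiological range.
    """

    response_gain: float = 0.7
    response_phase_deg: float = 0.0
    saccade_rate_hz: float = 0.2
    saccade_amplitude_deg: tuple[float, float] = (5.0, 2.0)  # mean, SD
    fixation_jitter_sd_deg: float = 0.02
    sample_rate_hz: float = 1000.0

    def __post_init__(self):
        if self.response_gain < 0:
            raise ValueError("gain must be non-negative")
        if self.fixation_jitter_sd_deg < 0:
            raise ValueError("jitter SD must be non-negative")


def generate_stimulus(frequency_hz: float, peak_velocity_deg_s: float = 10.0,
                      duration_s: float = 60.0,
                      sample_rate_hz: float = 1000.0) -> StimulusTrace:
    """Sinusoidal motion profile: velocity = peak*sin(2*pi*f*t).

    Position is the integral, re-zeroed to zero mean over the trace.
    """
    if frequency_hz <= 0 or peak_velocity_deg_s <= 0 or duration_s <= 0 or sample_rate_hz <= 0:
        raise ValueError("all stimulus parameters must be positive")
    if sample_rate_hz < 10 * frequency_hz:
        raise ValueError("sample rate too low for the stimulus frequency")
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    w = 2.0 * np.pi * frequency_hz
    vel = peak_velocity_deg_s * np.sin(w * t)
    pos = -(peak_velocity_deg_s / w) * np.cos(w * t)
    pos -= pos.mean()
    return StimulusTrace(time_s=t, position_deg=pos, velocity_deg_s=vel,
                         frequency_hz=frequency_hz,
                         peak_velocity_deg_s=peak_velocity_deg_s)


def generate_eye_trace(stimulus: StimulusTrace, spec: EyeKinematicsSpec | None = None,
                       seed: int | None = None,
                       recenter_range_deg: float = 5.0) -> EyeTrace:
    """Eye position responding to the stimulus with the specified kinematics.

    Slow-phase eye velocity is ``-gain * peak * sin(2*pi*f*t + phase)``
    (antiphase = compensatory; a positive ``response_phase_deg`` is a phase
    lead).  Saccades are 20 ms linear ramp steps at Poisson times; when the
    accumulated saccadic offset exceeds ``recenter_range_deg`` the next
    saccade is directed back toward center, emulating resetting quick
    phases.  White fixation jitter is added to position.
    """
    if spec is None:
        spec = EyeKinematicsSpec()
    if spec.sample_rate_hz < 10 * 2 * stimulus.frequency_hz:
        raise ValueError("eye sample rate too low for the stimulus frequency")
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate_hz
    duration = stimulus.time_s[-1] + (stimulus.time_s[1] - stimulus.time_s[0])
    t = np.arange(0.0, duration, 1.0 / fs)
    w = 2.0 * np.pi * stimulus.frequency_hz
    ph = np.deg2rad(spec.response_phase_deg)
    amp = spec.response_gain * stimulus.peak_velocity_deg_s / w
    pos = amp * np.cos(w * t + ph)
    pos -= pos.mean()

    n_sacc = rng.poisson(spec.saccade_rate_hz * duration)
    times = np.sort(rng.uniform(0.0, duration, n_sacc))
    mean_a, sd_a = spec.saccade_amplitude_deg
    offset = 0.0
    ramp_s = 0.020
    sacc = np.zeros_like(t)
    for t0 in times:
        a = abs(rng.normal(mean_a, sd_a))
        if abs(offset) > recenter_range_deg:
            sign = -np.sign(offset)
        else:
            sign = rng.choice([-1.0, 1.0])
        a *= sign
        sacc += a * np.clip((t - t0) / ramp_s, 0.0, 1.0)
        offset += a
    pos = pos + sacc
    if spec.fixation_jitter_sd_deg > 0:
        pos = pos + rng.normal(0.0, spec.fixation_jitter_sd_deg, t.size)
    return EyeTrace(time_s=t, position_deg=pos, sample_rate_hz=fs)


def project_to_cameras(eye: EyeTrace, rig: CameraRig | None = None,
                       r_p_mm: float = 1.25, pixel_noise_sd: float = 0.3,
                       seed: int | None = None,
                       image_shape: tuple[int, int] = (480, 640),
                       latency_s: float = 0.0,
                       clock_drift: float = 0.0) -> PupilFrameSeries:
    """Dual-camera pupil/CR pixel landmarks for an eye trace, at 30 frames/s.

    The eye angle maps to camera-axis angles ``theta_2 = eye + alpha/2``
    and ``theta_1 = alpha - theta_2`` (symmetric-zero convention), giving
    ``delta_i = R_p * sin(theta_i)`` converted to pixels.  Each camera's
    reference CR sits at its image center; the pupil landmark is CR +
    delta, with independent seeded pixel noise on both landmarks.  Frame
    timestamps are in the camera clock: frame k is exposed at sensor time
    ``latency_s + (1 + clock_drift) * k / 30`` but stamped ``k / 30``.
    Frames whose angle leaves the validity range are flagged, not clipped.
    """
    if rig is None:
        rig = CameraRig()
    if r_p_mm <= 0:
        raise ValueError("r_p_mm must be positive")
    rng = np.random.default_rng(seed)
    frame_dt = 1.0 / rig.frame_rate_hz
    t_cam = np.arange(0.0, eye.time_s[-1] - latency_s, frame_dt)
    t_sensor = latency_s + (1.0 + clock_drift) * t_cam
    ang = np.interp(t_sensor, eye.time_s, eye.position_deg)

    alpha = rig.inter_camera_angle_deg
    theta2 = rig.sign * ang + alpha / 2.0
    valid = (ang > alpha / 2.0 - 60.0) & (ang < alpha / 2.0 + 60.0)
    d1, d2 = forward_deltas(theta2, r_p_mm, rig)
    d_px = np.stack([d1, d2], axis=1) / rig.pixel_scale_mm_per_px

    h, wid = image_shape
    center = np.array([wid / 2.0, h / 2.0])
    n = t_cam.size
    cr = np.broadcast_to(center, (n, 2, 2)).copy()
    cr += rng.normal(0.0, pixel_noise_sd, cr.shape)
    pupil = cr.copy()
    pupil[:, :, 0] += d_px
    pupil += rng.normal(0.0, pixel_noise_sd, pupil.shape)
    return PupilFrameSeries(time_s=t_cam, pupil_px=pupil, cr_px=cr,
                            pixel_scale_mm_per_px=rig.pixel_scale_mm_per_px,
                            valid=valid)


@dataclass
class EyeImageSpec:
    """Rendering parameters for synthetic eye-camera frames."""

    shape: tuple[int, int] = (480, 640)
    iris_gray: float = 140.0
    pupil_depth: float = 110.0  # gray-level drop inside the pupil
    pupil_axes_px: tuple[float, float] = (40.0, 30.0)  # semi-axes (x, y)
    pupil_orientation_deg: float = 0.0
    edge_softness_px: float = 1.5
    cr_level: float = 250.0  # near-saturation peak of the specular CR blob
    cr_sigma_px: float = 2.5
    distractor_offset_px: tuple[float, float] = (-40.0, 0.0)
    noise_sd: float = 2.0


def _render_one(pupil_xy, cr_xy, spec: EyeImageSpec, rng) -> np.ndarray:
    h, w = spec.shape
    ax, ay = spec.pupil_axes_px
    px, py = pupil_xy
    if not (ax < px < w - ax and ay < py < h - ay):
        raise ValueError("pupil ellipse exceeds the image bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), spec.iris_gray, dtype=float)

    phi = np.deg2rad(spec.pupil_orientation_deg)
    dx, dy = xx - px, yy - py
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    r = np.sqrt((u / ax) ** 2 + (v / ay) ** 2)
    # signed distance from the ellipse edge in ~pixels, for a soft boundary
    d = (r - 1.0) * min(ax, ay)
    img -= spec.pupil_depth / (1.0 + np.exp(d / spec.edge_softness_px))

    # specular highlights saturate: composite with max, not addition
    for cx, cy in (cr_xy, (cr_xy[0] + spec.distractor_offset_px[0],
                           cr_xy[1] + spec.distractor_offset_px[1])):
        blob = spec.cr_level * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                      / (2.0 * spec.cr_sigma_px**2))
        img = np.maximum(img, blob)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_eye_frames(frames: PupilFrameSeries, image_spec: EyeImageSpec | None = None,
                      seed: int | None = None,
                      indices=None) -> np.ndarray:
    """Render grayscale image pairs for the landmark series.

    Returns an array of shape (n_frames, 2 cameras, H, W), uint8.  Each
    image holds a dark pupil ellipse, a bright Gaussian reference CR, and a
    displaced distractor CR (the reflection of the opposite camera's LED).
    Deterministic under a fixed seed.
    """
    if image_spec is None:
        image_spec = EyeImageSpec()
    rng = np.random.default_rng(seed)
    idx = np.arange(len(frames)) if indices is None else np.asarray(indices, int)
    h, w = image_spec.shape
    out = np.empty((idx.size, 2, h, w), dtype=np.uint8)
    for row, i in enumerate(idx):
        for cam in range(2):
            out[row, cam] = _render_one(frames.pupil_px[i, cam],
                                        frames.cr_px[i, cam], image_spec, rng)
    return out


def generate_overhead_motion(activity_schedule, frame_shape: tuple[int, int] = (64, 64),
                             seed: int | None = None, frame_rate_hz: float = 30.0,
                             noise_sd: float = 1.0):
    """Overhead-video frames of a blob whose mobility follows a schedule.

    ``activity_schedule`` is a list of ``(duration_s, displacement_sd_px)``
    steps.  Returns ``(frames, labels, frame_rate_hz)`` where ``frames`` is
    a uint8 array (n, H, W) and ``labels`` gives the schedule level index
    per frame (ground truth for motion-index classification).
    """
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    pos = np.array([w / 2.0, h / 2.0])
    sigma = max(2.0, min(h, w) / 12.0)
    frames, labels = [], []
    for level, (dur, disp_sd) in enumerate(activity_schedule):
        n = int(round(dur * frame_rate_hz))
        for _ in range(n):
            if disp_sd > 0:
                pos = pos + rng.normal(0.0, disp_sd, 2)
                pos[0] = np.clip(pos[0], sigma, w - sigma)
                pos[1] = np.clip(pos[1], sigma, h - sigma)
            img = 30.0 + 120.0 * np.exp(
                -((xx - pos[0]) ** 2 + (yy - pos[1]) ** 2) / (2 * sigma**2))
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, img.shape)
            frames.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(level)
    return np.asarray(frames), np.asarray(labels), frame_rate_hz


@dataclass
class SessionBundle:
    """A complete synthetic session: ground truth plus all observables."""

    stimulus: StimulusTrace
    eye: EyeTrace  # ground truth at sensor rate
    sensor: SensorTrace
    camera: PupilFrameSeries
    flash_frame_indices: np.ndarray  # LED sync flashes, video frame index
    camera_brightness: np.ndarray  # per-frame mean intensity incl. flashes
    kinematics: EyeKinematicsSpec
    sensor_spec: AMRSensorSpec
    geometry: MagnetGeometry
    rig: CameraRig
    k_true_deg_per_mV: float
    camera_latency_s: float
    clock_drift: float
    seed: int | None
    overhead: tuple | None = None


def generate_session(
    frequency_hz: float = 1.0,
    peak_velocity_deg_s: float = 10.0,
    duration_s: float = 60.0,
    kinematics: EyeKinematicsSpec | None = None,
    sensor_spec: AMRSensorSpec | None = None,
    geometry: MagnetGeometry | None = None,
    rig: CameraRig | None = None,
    r_p_mm: float = 1.25,
    pixel_noise_sd: float = 0.3,
    camera_latency_s: float = 0.40,
    clock_drift: float = 0.0,
    flash_rate_hz: float = 1.0,
    include_overhead: bool = False,
    seed: int | None = 0,
) -> SessionBundle:
    """Generate a full calibration session with known ground truth.

    Defaults emulate the standard calibration condition: 60 s of a 1 Hz,
    +/-10 deg/s sinusoidal vestibular stimulus in the light, sensor at 3 mm
    vertical distance (in-vivo-like sensitivity), 30 frames/s video with a
    0.4 s camera latency, and 1 Hz / 30 ms LED sync flashes recorded both
    as TTL pulses (sensor clock) and as brightened video frames.

    ``k_true_deg_per_mV`` is the reciprocal small-angle sensitivity of the
    sensor channel operating at its zero crossing (channel 1 for the
    default mounting offset of zero).
    """
    if kinematics is None:
        kinematics = EyeKinematicsSpec()
    if sensor_spec is None:
        sensor_spec = AMRSensorSpec()
    if geometry is None:
        geometry = MagnetGeometry(vertical_distance_mm=3.0)
    if rig is None:
        rig = CameraRig()
    ss = np.random.SeedSequence(seed)
    s_eye, s_sens, s_cam, s_over = [int(c.generate_state(1)[0] % (2**31))
                                    for c in ss.spawn(4)]

    stimulus = generate_stimulus(frequency_hz, peak_velocity_deg_s, duration_s,
                                 kinematics.sample_rate_hz)
    eye = generate_eye_trace(stimulus, kinematics, seed=s_eye)
    sensor = simulate_sensor_trace(eye, sensor_spec, geometry, seed=s_sens,
                                   ttl_rate_hz=flash_rate_hz)
    camera = project_to_cameras(eye, rig, r_p_mm=r_p_mm,
                                pixel_noise_sd=pixel_noise_sd, seed=s_cam,
                                latency_s=camera_latency_s,
                                clock_drift=clock_drift)

    # LED flashes: TTL times are in the sensor clock; in the camera clock a
    # flash at t_ttl illuminates the frame stamped (t_ttl - latency)/(1+drift).
    ttl = sensor.ttl_pulse_times_s
    t_cam_flash = (ttl - camera_latency_s) / (1.0 + clock_drift)
    in_range = (t_cam_flash >= 0) & (t_cam_flash <= camera.time_s[-1])
    flash_idx = np.unique(np.round(t_cam_flash[in_range] * rig.frame_rate_hz).astype(int))
    flash_idx = flash_idx[flash_idx < len(camera)]
    brightness_rng = np.random.default_rng(s_cam + 1)
    brightness = 120.0 + brightness_rng.normal(0.0, 1.0, len(camera))
    brightness[flash_idx] += 40.0

    k_true = 1.0 / small_angle_sensitivity(sensor_spec, geometry, channel=0)

    overhead = None
    if include_overhead:
        third = duration_s / 3.0
        schedule = [(third, 0.0), (third, 1.0), (third, 3.0)]
        overhead = generate_overhead_motion(schedule, seed=s_over)

    return SessionBundle(
        stimulus=stimulus, eye=eye, sensor=sensor, camera=camera,
        flash_frame_indices=flash_idx, camera_brightness=brightness,
        kinematics=kinematics, sensor_spec=sensor_spec, geometry=geometry,
        rig=rig, k_true_deg_per_mV=k_true, camera_latency_s=camera_latency_s,
        clock_drift=clock_drift, seed=seed, overhead=overhead,
    )
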