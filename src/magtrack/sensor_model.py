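"""Forward model of the two-channel AMR angle sensor over a rotating magnet.

An anisotropic-magnetoresistive (AMR) angle sensor contains two Wheatstone
bridges of magnetoresistive elements rotated 45 degrees relative to each
other.  Each bridge outputs a differential voltage proportional to
``sin(2*theta_m)`` where ``theta_m`` is the in-plane angle of the external
magnetic field -- here, the field of a small magnet implanted on the eye.
The response is therefore 180-degree periodic and, within roughly +/-22.5
degrees of a zero crossing, close to linear in angle.

The module provides:

* :func:`amr_response` -- the ideal two-channel voltage at a magnet angle;
* :func:`sensitivity_profile` -- effective response amplitude as a function
  of magnet-sensor geometry (vertical distance, horizontal offset), anchored
  to bench measurements of the sensor (224.7, 127.0 and 28.1 mV/deg mean
  sensitivity at 0, 3 and 5 mm vertical distance);
* :func:`dipole_field_angle` -- a point-dipole variant used to model
  horizontal offset, lever-arm rotation and magnet tilt;
* :func:`simulate_sensor_trace` -- sensor voltages for a ground-truth eye
  trace, with seeded Gaussian noise and an optional TTL sync-pulse train;
* :func:`estimate_sensitivity` -- the zero-crossing mean-slope sensitivity
  estimator (mean absolute slope within +/-22.5 deg of each zero crossing).

For a pure ``A*sin(2*theta_deg)`` channel the mean absolute slope over
+/-22.5 deg around a crossing has the closed form ``A*sqrt(2)/45`` mV/deg,
used to convert between amplitude and mean sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import EyeTrace, SensorTrace

__all__ = [
    "AMRSensorSpec",
    "MagnetGeometry",
    "MEAN_SLOPE_PER_AMPLITUDE",
    "SENSITIVITY_ANCHORS_MV_PER_DEG",
    "amr_response",
    "sensitivity_profile",
    "dipole_field_angle",
    "simulate_sensor_trace",
    "estimate_sensitivity",
]

#: Mean |dV/dtheta| over +/-22.5 deg around a zero crossing of A*sin(2*theta),
#: per unit amplitude A:  (1/45) * integral of (pi/90)*cos(pi*theta/90)
#: over [-22.5, 22.5] = sqrt(2)/45  (mV/deg per mV).
MEAN_SLOPE_PER_AMPLITUDE = np.sqrt(2.0) / 45.0

#: Bench-measured channel-mean sensitivity (mV/deg) vs vertical magnet-sensor
#: distance (mm) for the cylinder magnet.
SENSITIVITY_ANCHORS_MV_PER_DEG = {0.0: 224.7, 3.0: 127.0, 5.0: 28.1}

#: sin(2*theta) amplitude (mV) that reproduces the 0 mm anchor sensitivity.
REFERENCE_AMPLITUDE_MV = SENSITIVITY_ANCHORS_MV_PER_DEG[0.0] / MEAN_SLOPE_PER_AMPLITUDE


@dataclass
class AMRSensorSpec:
    """Parameters of the two-channel AMR sensor response.

    ``peak_amplitude_mV`` is the sin(2*theta) amplitude A at the reference
    geometry (magnet adjacent to the sensor, on-axis).  The two channels'
    angular tuning differs by exactly 45 degrees.
    """

    channel_phase_deg: tuple[float, float] = (0.0, 45.0)
    peak_amplitude_mV: float = REFERENCE_AMPLITUDE_MV
    baseline_offset_mV: tuple[float, float] = (0.0, 0.0)
    noise_sd_mV: float = 2.0

    def __post_init__(self):
        if len(self.channel_phase_deg) != 2:
            raise ValueError("exactly two channels are modeled")
        dphi = abs(self.channel_phase_deg[1] - self.channel_phase_deg[0])
        if not np.isclose(dphi % 180.0, 45.0) and not np.isclose(dphi % 180.0, 135.0):
            raise ValueError("channel phases must differ by 45 degrees")
        if self.peak_amplitude_mV <= 0:
            raise ValueError("peak_amplitude_mV must be positive")
        if self.noise_sd_mV < 0:
            raise ValueError("noise_sd_mV must be non-negative")


@dataclass
class MagnetGeometry:
    """Relative placement of the implanted magnet and the AMR sensor.

    ``vertical_distance_mm`` is the distance from the magnet plane to the
    sensor plane; ``horizontal_offset_mm`` the in-plane displacement of the
    sensor center from the magnet's rotation axis; ``lever_arm_mm`` the
    displacement of the magnet itself from the rotation axis (the eye
    radius, about 1.5 mm in the mouse, when the magnet sits on the globe);
    ``tilt_deg`` the tilt of the magnet's N-S axis out of the sensor plane.
    """

    vertical_distance_mm: float = 3.0
    horizontal_offset_mm: float = 0.0
    tilt_deg: float = 0.0
    lever_arm_mm: float = 0.0
    dipole_strength: float = 1.0

    def __post_init__(self):
        if self.vertical_distance_mm < 0:
            raise ValueError("vertical_distance_mm must be non-negative")
        if not -90.0 <= self.tilt_deg <= 90.0:
            raise ValueError("tilt_deg must lie in [-90, 90]")


def amr_response(theta_m, spec: AMRSensorSpec | None = None) -> np.ndarray:
    """Two-channel AMR voltage (mV) at magnet angle ``theta_m`` (deg).

    Channel ``c`` returns ``A*sin(2*(theta_m - phase_c)) + offset_c``.
    Accepts a scalar or array angle; output has a trailing channel axis of
    length 2.  The response is 180-degree periodic.
    """
    if spec is None:
        spec = AMRSensorSpec()
    theta = np.asarray(theta_m, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta_m must be finite")
    phases = np.asarray(spec.channel_phase_deg)
    offsets = np.asarray(spec.baseline_offset_mV)
    arg = np.deg2rad(2.0 * (theta[..., None] - phases))
    return spec.peak_amplitude_mV * np.sin(arg) + offsets


def dipole_field_angle(magnet: MagnetGeometry, theta_m) -> np.ndarray:
    """In-plane magnetic field angle (deg) at the sensor center.

    The magnet is a point dipole whose moment lies at in-plane angle
    ``theta_m``, tilted out of plane by ``magnet.tilt_deg``, located
    ``lever_arm_mm`` from the rotation axis (rotating with the magnet).
    The sensor center sits at ``(horizontal_offset_mm, 0,
    vertical_distance_mm)`` relative to the rotation axis.

    Returns ``atan2(B_y, B_x)`` in degrees, wrapped to [0, 360).  For an
    on-axis magnet with zero lever arm this is exactly ``theta_m + 180``
    (the on-axis dipole field is antiparallel to the in-plane moment).
    """
    theta = np.deg2rad(np.asarray(theta_m, dtype=float))
    tilt = np.deg2rad(magnet.tilt_deg)
    # moment direction (unit), tilted out of the z=0 plane
    m = magnet.dipole_strength * np.stack(
        [
            np.cos(tilt) * np.cos(theta),
            np.cos(tilt) * np.sin(theta),
            np.full_like(theta, np.sin(tilt)),
        ],
        axis=-1,
    )
    # magnet center rotates about the axis at the lever-arm radius
    pos = magnet.lever_arm_mm * np.stack(
        [np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1
    )
    sensor = np.array([magnet.horizontal_offset_mm, 0.0, magnet.vertical_distance_mm])
    r = sensor - pos
    rnorm = np.linalg.norm(r, axis=-1, keepdims=True)
    if np.any(rnorm == 0.0):
        raise ValueError("sensor coincides with the dipole location")
    rhat = r / rnorm
    b = (3.0 * np.sum(m * rhat, axis=-1, keepdims=True) * rhat - m) / rnorm**3
    return np.rad2deg(np.arctan2(b[..., 1], b[..., 0])) % 360.0


def _vertical_attenuation() -> PchipInterpolator:
    d = np.array(sorted(SENSITIVITY_ANCHORS_MV_PER_DEG))
    s = np.array([SENSITIVITY_ANCHORS_MV_PER_DEG[k] for k in d])
    # monotone piecewise-cubic through the bench anchors, relative to 0 mm
    return PchipInterpolator(d, s / s[0], extrapolate=False)


_VERT_ATT = _vertical_attenuation()
_MAX_ANCHOR_MM = max(SENSITIVITY_ANCHORS_MV_PER_DEG)


def _angle_gain(magnet: MagnetGeometry, half_range_deg: float = 22.5) -> float:
    """Mean |d(field angle)/d(magnet angle)| over a +/-``half_range_deg`` sweep.

    Equals 1 for on-axis geometry; off-axis placement distorts the field
    rotation seen by the sensor.
    """
    theta = np.linspace(-half_range_deg, half_range_deg, 181)
    phi = np.unwrap(np.deg2rad(dipole_field_angle(magnet, theta)))
    return float(np.mean(np.abs(np.gradient(np.rad2deg(phi), theta))))


def _field_magnitude_ratio(magnet: MagnetGeometry, half_range_deg: float = 22.5) -> float:
    """Mean dipole field magnitude at the sensor, relative to on-axis.

    The bridge output amplitude falls off with the driving field strength
    once the field weakens below the sensor's saturation regime; the ratio
    of mean field magnitude over the sweep to the on-axis magnitude at the
    same vertical distance is a simple monotone proxy for that loss.
    """
    theta = np.deg2rad(np.linspace(-half_range_deg, half_range_deg, 181))
    tilt = np.deg2rad(magnet.tilt_deg)
    m = np.stack(
        [np.cos(tilt) * np.cos(theta), np.cos(tilt) * np.sin(theta),
         np.full_like(theta, np.sin(tilt))], axis=-1)
    pos = magnet.lever_arm_mm * np.stack(
        [np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)
    sensor = np.array([magnet.horizontal_offset_mm, 0.0, magnet.vertical_distance_mm])
    r = sensor - pos
    rnorm = np.linalg.norm(r, axis=-1, keepdims=True)
    if np.any(rnorm == 0.0):
        raise ValueError("sensor coincides with the dipole location")
    rhat = r / rnorm
    b = (3.0 * np.sum(m * rhat, axis=-1, keepdims=True) * rhat - m) / rnorm**3
    bmag = float(np.mean(np.linalg.norm(b, axis=-1)))
    d = max(magnet.vertical_distance_mm, 1e-6)
    return bmag * d**3


def sensitivity_profile(geometry: MagnetGeometry, spec: AMRSensorSpec | None = None) -> float:
    """Effective sin(2*theta) amplitude (mV) at the given geometry.

    The reference amplitude is attenuated by (a) a monotone curve through
    the bench sensitivities at 0/3/5 mm vertical distance (held constant
    beyond 5 mm), and (b) the point-dipole field-magnitude ratio for any
    horizontal offset or lever arm (clipped at 1: a stronger-than-on-axis
    field cannot exceed the saturated response).  At the reference geometry
    the attenuation is 1.
    """
    if spec is None:
        spec = AMRSensorSpec()
    if geometry.vertical_distance_mm < 0:
        raise ValueError("vertical distance must be non-negative")
    d = min(geometry.vertical_distance_mm, _MAX_ANCHOR_MM)
    att_v = float(_VERT_ATT(d))
    if geometry.horizontal_offset_mm == 0.0 and geometry.lever_arm_mm == 0.0:
        att_h = 1.0
    else:
        att_h = min(1.0, _field_magnitude_ratio(geometry))
    return spec.peak_amplitude_mV * att_v * att_h


def simulate_sensor_trace(
    eye: EyeTrace,
    spec: AMRSensorSpec | None = None,
    geometry: MagnetGeometry | None = None,
    seed: int | None = None,
    mounting_offset_deg: float = 0.0,
    ttl_rate_hz: float | None = None,
) -> SensorTrace:
    """Simulate the two-channel sensor voltages for a ground-truth eye trace.

    The magnet angle is the eye angle plus a mounting offset (surgical
    alignment is approximate).  The response amplitude comes from
    :func:`sensitivity_profile`; seeded Gaussian noise of ``spec.noise_sd_mV``
    is added per sample.  When ``ttl_rate_hz`` is given, a pulse train at
    that rate (starting at t=0) is recorded as TTL onset times.
    """
    if spec is None:
        spec = AMRSensorSpec()
    if geometry is None:
        geometry = MagnetGeometry(vertical_distance_mm=0.0)
    if len(eye) == 0:
        raise ValueError("eye trace is empty")
    amp = sensitivity_profile(geometry, spec)
    eff = AMRSensorSpec(
        channel_phase_deg=spec.channel_phase_deg,
        peak_amplitude_mV=amp,
        baseline_offset_mV=spec.baseline_offset_mV,
        noise_sd_mV=spec.noise_sd_mV,
    )
    v = amr_response(eye.position_deg + mounting_offset_deg, eff)
    if spec.noise_sd_mV > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, spec.noise_sd_mV, size=v.shape)
    ttl = None
    if ttl_rate_hz:
        ttl = np.arange(eye.time_s[0], eye.time_s[-1], 1.0 / ttl_rate_hz)
    return SensorTrace(
        time_s=eye.time_s.copy(),
        v_mV=v,
        sample_rate_hz=eye.sample_rate_hz,
        ttl_pulse_times_s=ttl,
    )


def small_angle_sensitivity(spec: AMRSensorSpec, geometry: MagnetGeometry,
                            channel: int = 0) -> float:
    """Slope dV/dtheta (mV/deg) of one channel at its zero crossing.

    For channel phase p the response is A*sin(2*(theta-p)); the slope at
    theta = p is A*pi/90 mV/deg.  This is the local (small-angle)
    sensitivity relevant when the eye operates near a crossing, and its
    reciprocal is the true calibration factor k (deg/mV).
    """
    amp = sensitivity_profile(geometry, spec)
    return amp * np.pi / 90.0


def estimate_sensitivity(
    angle_sweep_deg,
    voltage_sweep_mV,
    half_range_deg: float = 22.5,
    slope_window_deg: float | None = None,
) -> np.ndarray:
    """Zero-crossing mean-slope sensitivity (mV/deg), per channel.

    For each channel, locates the zero crossings of the voltage sweep and
    averages the absolute local slope within ``half_range_deg`` of each
    crossing, then averages over crossings.  Channels with no crossing in
    the sweep return NaN ("not estimable") rather than raising.

    The local slope uses centered finite differences on the sweep grid by
    default; pass ``slope_window_deg`` to instead fit a least-squares line
    within a +/- window at each point (useful on noisy sweeps).
    """
    theta = np.asarray(angle_sweep_deg, dtype=float)
    if theta.ndim != 1 or theta.size < 3:
        raise ValueError("angle sweep must be 1-D with at least 3 samples")
    dth = np.diff(theta)
    if not (np.all(dth > 0) or np.all(dth < 0)):
        raise ValueError("angle sweep must be strictly monotone")
    v = np.asarray(voltage_sweep_mV, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.shape[0] != theta.size:
        raise ValueError("voltage sweep length must match angle sweep")

    out = np.full(v.shape[1], np.nan)
    for c in range(v.shape[1]):
        vc = v[:, c]
        sgn = np.sign(vc)
        flips = np.flatnonzero(sgn[:-1] * sgn[1:] < 0)
        crossings = [
            theta[i] - vc[i] * (theta[i + 1] - theta[i]) / (vc[i + 1] - vc[i])
            for i in flips
        ]
        crossings += list(theta[np.flatnonzero(vc == 0.0)])
        if not crossings:
            continue
        if slope_window_deg is None:
            slope = np.gradient(vc, theta)
        else:
            slope = _windowed_slope(theta, vc, slope_window_deg)
        per_crossing = []
        for z in crossings:
            sel = np.abs(theta - z) <= half_range_deg
            if sel.any():
                per_crossing.append(np.mean(np.abs(slope[sel])))
        if per_crossing:
            out[c] = float(np.mean(per_crossing))
    return out


def _windowed_slope(theta: np.ndarray, v: np.ndarray, half_window_deg: float) -> np.ndarray:
    slope = np.empty_like(v)
    for i, t0 in enumerate(theta):
        sel = np.abs(theta - t0) <= half_window_deg
        x = theta[sel]
        if x.size < 2:
            slope[i] = np.nan
            continue
        xm = x - x.mean()
        slope[i] = np.dot(xm, v[sel]) / np.dot(xm, xm)
    return slope
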