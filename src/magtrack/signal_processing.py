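"""Trace conditioning and video-sensor alignment.

The measurement chain records eye position twice: at video rate (30 Hz,
camera clock) and at sensor rate (1 kHz default, acquisition clock).  This
module provides the conditioning steps shared by calibration and analysis:

* zero-phase Butterworth low-pass filtering (100 Hz default, order 4,
  applied forward-backward);
* differentiation by the least-squares slope in a 50 ms sliding window --
  exact on linear signals, and attenuating a sinusoid of frequency f by the
  known factor sinc(f * T_window);
* velocity-threshold artifact/saccade exclusion (50 deg/s on video-derived
  eye velocity, 5 mV/ms on differentiated sensor voltage), with padding and
  the union rule: a segment excluded in either stream is excluded in both;
* LED sync-flash alignment: a 1 Hz train of 30 ms flashes is visible in the
  video and recorded as TTL pulses by the acquisition system; regressing
  matched flash times gives the inter-clock offset and drift, after which
  the video-derived eye trace is upsampled onto the sensor timeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import binary_dilation
from scipy.optimize import brentq

from .core import EyeTrace, ExclusionMask, SensorTrace, VelocityTrace

__all__ = [
    "AlignedSession",
    "lowpass_filter",
    "differentiate",
    "detect_artifacts",
    "align_streams",
    "VIDEO_VELOCITY_THRESHOLD_DEG_S",
    "SENSOR_VELOCITY_THRESHOLD_MV_MS",
]

#: Velocity thresholds for automatic saccade/artifact exclusion.
VIDEO_VELOCITY_THRESHOLD_DEG_S = 50.0
SENSOR_VELOCITY_THRESHOLD_MV_MS = 5.0


def lowpass_filter(values, sample_rate_hz: float, cutoff_hz: float = 100.0,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (DC gain 1, -3 dB at cutoff).

    Applied forward-backward (filtfilt) so the passband is phase-neutral;
    note the two passes place the -3 dB point of the cascade at the cutoff
    of a single pass only approximately -- the single-pass design cutoff is
    adjusted so the zero-phase response is -3 dB at ``cutoff_hz``.
    """
    x = np.asarray(values, dtype=float)
    nyq = sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")

    # filtfilt squares the magnitude response, so the single-pass design
    # cutoff must sit above cutoff_hz for the zero-phase cascade to be -3 dB
    # there; solve for it on the measured digital response (this also
    # absorbs bilinear warping near Nyquist)
    def two_pass_gain_at_cutoff(wc: float) -> float:
        sos = sps.butter(order, wc, btype="low", fs=sample_rate_hz, output="sos")
        _, h = sps.sosfreqz(sos, worN=[cutoff_hz], fs=sample_rate_hz)
        return float(np.abs(h[0]) ** 2)

    target = 1.0 / np.sqrt(2.0)
    lo, hi = cutoff_hz, nyq * 0.999
    if two_pass_gain_at_cutoff(hi) < target:
        wc = hi  # cutoff too close to Nyquist to hit -3 dB exactly
    else:
        wc = brentq(lambda w: two_pass_gain_at_cutoff(w) - target, lo, hi,
                    xtol=1e-3)
    sos = sps.butter(order, wc, btype="low", fs=sample_rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def _window_samples(window_ms: float, sample_rate_hz: float) -> int:
    n = int(round(window_ms * 1e-3 * sample_rate_hz))
    n = max(n, 3)
    return n if n % 2 == 1 else n + 1


def differentiate(trace, window_ms: float = 50.0) -> VelocityTrace:
    """Per-sample least-squares slope over a centered sliding window.

    ``trace`` may be an :class:`EyeTrace` (output deg/s), a
    :class:`SensorTrace` (output mV/s, both channels), or a
    ``(time_s, values, units)`` tuple.  The window is the odd sample count
    nearest ``window_ms``; edge samples use shrunken (boundary-clipped)
    windows.  Exact on polynomials of degree <= 1.
    """
    if isinstance(trace, EyeTrace):
        t, x, units = trace.time_s, trace.position_deg, "deg/s"
        fs = trace.sample_rate_hz
    elif isinstance(trace, SensorTrace):
        t, x, units = trace.time_s, trace.v_mV, "mV/s"
        fs = trace.sample_rate_hz
    else:
        t, x, units = trace
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        fs = 1.0 / (t[1] - t[0])
    n = _window_samples(window_ms, fs)
    if n > t.size:
        raise ValueError("window longer than trace")
    dt = 1.0 / fs
    x2 = x[:, None] if x.ndim == 1 else x
    out = sps.savgol_filter(x2, n, polyorder=1, deriv=1, delta=dt,
                            axis=0, mode="interp")
    # shrunken centered windows at the edges (savgol 'interp' instead
    # extrapolates the full first/last window fit)
    h = n // 2
    for i in range(h):
        for j, sl in ((i, slice(0, i + h + 1)), (x2.shape[0] - 1 - i, slice(-(i + h + 1), None))):
            ts = t[sl] - t[sl].mean()
            denom = np.dot(ts, ts)
            if denom > 0:
                out[j] = ts @ x2[sl] / denom
    value = out[:, 0] if x.ndim == 1 else out
    return VelocityTrace(time_s=t.copy(), value=value, units=units, window_ms=window_ms)


def detect_artifacts(velocity: VelocityTrace, threshold: float,
                     pad_ms: float = 50.0, source: str = "video") -> ExclusionMask:
    """Mark samples whose |velocity| exceeds ``threshold``, padded.

    ``threshold`` is in the velocity trace's units.  Supra-threshold samples
    are dilated by ``pad_ms`` on each side; overlapping intervals merge.  A
    two-channel velocity trace is excluded where either channel exceeds the
    threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = velocity.value
    over = (np.abs(v) > threshold) | ~np.isfinite(v)
    if over.ndim == 2:
        over = over.any(axis=1)
    if velocity.time_s.size > 1:
        fs = 1.0 / (velocity.time_s[1] - velocity.time_s[0])
    else:
        fs = 1.0
    pad = int(round(pad_ms * 1e-3 * fs))
    if pad > 0 and over.any():
        over = binary_dilation(over, structure=np.ones(2 * pad + 1, dtype=bool))
    return ExclusionMask(excluded=over, source=source, pad_ms=pad_ms)


@dataclass
class AlignedSession:
    """Video-derived eye and sensor voltages on a common (sensor) timeline."""

    time_s: np.ndarray
    eye_deg: np.ndarray
    v_mV: np.ndarray
    excluded: np.ndarray
    sample_rate_hz: float
    clock_offset_s: float
    clock_drift: float
    flash_residuals_s: np.ndarray

    @property
    def included(self) -> np.ndarray:
        return ~self.excluded

    def eye_trace(self) -> EyeTrace:
        return EyeTrace(self.time_s.copy(), self.eye_deg.copy(), self.sample_rate_hz)


def _match_flashes(video_times: np.ndarray, ttl_times: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pair video flash times with TTL times by nearest neighbor.

    A periodic sync train makes the pairing ambiguous up to whole periods;
    the camera stream is assumed to start after acquisition with a latency
    shorter than one sync period, so the coarse offset pairs the first
    video flash with the first TTL at or after it (offset in [0, period)).
    Nearest-neighbor matching with half-a-period slack then tolerates
    single missed detections in either stream.
    """
    period = float(np.median(np.diff(ttl_times))) if ttl_times.size > 1 else 1.0
    tol = 0.45 * period
    cand = ttl_times[ttl_times - video_times[0] >= -tol]
    anchor = cand[0] if cand.size else ttl_times[-1]
    offset = anchor - video_times[0]
    vsel, tsel = [], []
    used = set()
    for vt in video_times:
        i = int(np.argmin(np.abs(ttl_times - (vt + offset))))
        if i in used:
            continue
        if abs(ttl_times[i] - (vt + offset)) <= tol:
            vsel.append(vt)
            tsel.append(ttl_times[i])
            used.add(i)
    return np.asarray(vsel), np.asarray(tsel)


def align_streams(
    video_eye: EyeTrace,
    flash_indices,
    sensor: SensorTrace,
    ttl_times=None,
    video_mask: ExclusionMask | None = None,
    sensor_mask: ExclusionMask | None = None,
) -> AlignedSession:
    """Upsample the video-derived eye trace onto the sensor timeline.

    Flash frame-times (camera clock) are regressed against TTL pulse times
    (sensor clock): ``t_sensor = offset + (1 + drift) * t_video``.  The
    video timeline is re-expressed in sensor time and the eye positions are
    linearly interpolated to the sensor sample times.  Exclusion masks from
    either stream are carried over and OR-ed: a segment marked in either
    recording is excluded from both.
    """
    ttl = sensor.ttl_pulse_times_s if ttl_times is None else np.asarray(ttl_times, float)
    if ttl is None:
        raise ValueError("sensor TTL pulse times are required for alignment")
    flash_idx = np.asarray(flash_indices, dtype=int)
    vtimes = video_eye.time_s[flash_idx]
    vsel, tsel = _match_flashes(vtimes, np.asarray(ttl, float))
    if vsel.size < 2:
        raise ValueError(f"need >= 2 matched flashes, found {vsel.size}")
    slope, intercept = np.polyfit(vsel, tsel, 1)
    residuals = tsel - (intercept + slope * vsel)

    video_t_sensor = intercept + slope * video_eye.time_s
    # NaN gaps (invalid frames) are bridged by interpolation but stay
    # excluded; edge samples outside the overlap are held and excluded, so
    # downstream differentiation stays finite
    vpos = video_eye.position_deg
    vgap = ~np.isfinite(vpos)
    if vgap.any():
        if vgap.all():
            raise ValueError("video eye trace has no valid samples")
        vpos = np.interp(video_t_sensor, video_t_sensor[~vgap], vpos[~vgap])
    eye = np.interp(sensor.time_s, video_t_sensor, vpos)
    excluded = ((sensor.time_s < video_t_sensor[0])
                | (sensor.time_s > video_t_sensor[-1]))
    if vgap.any():
        gap = np.interp(sensor.time_s, video_t_sensor, vgap.astype(float))
        excluded |= gap > 0.0
    if sensor_mask is not None:
        excluded = excluded | sensor_mask.excluded
    if video_mask is not None:
        vm = np.interp(sensor.time_s, video_t_sensor,
                       video_mask.excluded.astype(float), left=1.0, right=1.0)
        excluded = excluded | (vm > 0.0)

    return AlignedSession(
        time_s=sensor.time_s.copy(),
        eye_deg=eye,
        v_mV=sensor.v_mV.copy(),
        excluded=excluded,
        sample_rate_hz=sensor.sample_rate_hz,
        clock_offset_s=float(intercept),
        clock_drift=float(slope - 1.0),
        flash_residuals_s=residuals,
    )
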