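"""Calibration of sensor voltages into angular eye position/velocity.

The magnet-sensor system outputs voltages in mV; calibration finds the
mapping to degrees by comparing against simultaneously recorded
video-oculography during a sinusoidal vestibular stimulus.  Two families of
methods are implemented:

**Position methods** regress video-derived eye position e(t) on the sensor
voltages m1(t), m2(t) over the aligned, desaccaded session:

* one-channel:  e_c(t) = k1_c * m_c(t) + k2_c, each channel separately; the
  channel more strongly correlated with the video position is selected and
  its slope k1 is the calibration factor (deg/mV);
* two-channel:  e(t) = k1*m1 + k2*m2 + k3, fitted by ridge regression with
  the penalty chosen by 10-fold cross-validation on contiguous time blocks,
  then refit on all data at the selected penalty;
* quadratic:    e(t) = k1*m1 + k2*m2 + k3*m1^2 + k4*m2^2 + k5, same ridge
  + CV procedure, for sessions where the operating point falls on a
  nonlinear part of the sin(2*theta) response.

**Velocity method**: both position recordings are differentiated (50 ms
sliding-window slope) and each fitted with a sine at the known stimulus
frequency; the calibration factor is the amplitude ratio A_vid / A_mag
(deg/mV) using the sensor channel with the higher sine-fit r^2.  Because
only amplitudes enter, this method does not require precise temporal
alignment of the two streams.

Day-to-day stability is summarized by the drift metric
``dk_n = |k_n - k_1| / k_1 * 100`` (percent change from the first day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge

from .core import EyeTrace, ExclusionMask, SensorTrace, VelocityTrace
from .signal_processing import AlignedSession, detect_artifacts, differentiate

__all__ = [
    "PositionCalibration",
    "VelocityCalibration",
    "CalibrationDrift",
    "DEFAULT_LAMBDA_GRID",
    "fit_position_one_channel",
    "fit_position_two_channel",
    "fit_position_quadratic",
    "fit_velocity_calibration",
    "apply_calibration",
    "calibration_drift",
]

#: 25-point log-spaced ridge penalty grid (after regressor standardization).
DEFAULT_LAMBDA_GRID = np.logspace(-6, 3, 25)


@dataclass
class PositionCalibration:
    """Fitted voltage-to-position model.

    ``coefficients`` are on the original (mV) scale:
    one_channel -> (k1_1, k2_1, k1_2, k2_2); two_channel -> (k1, k2, k3);
    quadratic -> (k1, k2, k3, k4, k5).
    """

    model: str  # one_channel | two_channel | quadratic
    coefficients: np.ndarray
    ridge_lambda: float | None = None
    best_channel: int | None = None  # 1-based, one_channel model only
    r_per_channel: tuple[float, float] | None = None
    variance_explained: float = 0.0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = {"one_channel": 4, "two_channel": 3, "quadratic": 5}
        if self.model not in expected:
            raise ValueError(f"unknown model {self.model!r}")
        if self.coefficients.size != expected[self.model]:
            raise ValueError(
                f"{self.model} expects {expected[self.model]} coefficients")

    @property
    def k(self) -> float:
        """Calibration factor (deg/mV): the selected channel's slope."""
        if self.model == "one_channel":
            return float(self.coefficients[0 if self.best_channel == 1 else 2])
        return float(self.coefficients[0])


@dataclass
class VelocityCalibration:
    """Amplitude-ratio calibration from differentiated traces."""

    a_vid_deg_s: float
    a_mag_mV_s: float
    chosen_channel: int  # 1-based
    r2_per_channel: tuple[float, float]
    r2_video: float = 1.0
    signed: bool = True

    @property
    def factor_deg_per_mV(self) -> float:
        return self.a_vid_deg_s / self.a_mag_mV_s


@dataclass
class CalibrationDrift:
    """Per-day calibration factors and percent drift from day 1."""

    k_series: np.ndarray
    delta_pct_series: np.ndarray


def _masked(session: AlignedSession, mask: ExclusionMask | None):
    keep = session.included
    if mask is not None:
        keep = keep & mask.included
    e = session.eye_deg[keep]
    m = session.v_mV[keep]
    ok = np.isfinite(e) & np.all(np.isfinite(m), axis=1)
    return e[ok], m[ok]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def fit_position_one_channel(session: AlignedSession,
                             mask: ExclusionMask | None = None) -> PositionCalibration:
    """Fit e(t) = k1*m_c(t) + k2 for each channel; select the better one.

    Selection maximizes |r| with the video-derived position (implant
    polarity can invert the sign).  A constant (degenerate) channel is
    marked unusable via r = NaN.
    """
    e, m = _masked(session, mask)
    if e.size <= 100:
        raise ValueError(f"too few included samples ({e.size}) for calibration")
    coefs, rs = [], []
    for c in range(2):
        r = _pearson(e, m[:, c])
        rs.append(r)
        if np.isnan(r):
            coefs.extend([np.nan, np.nan])
        else:
            k1, k2 = np.polyfit(m[:, c], e, 1)
            coefs.extend([k1, k2])
    if np.all(np.isnan(rs)):
        raise ValueError("both sensor channels are degenerate")
    best = int(np.nanargmax(np.abs(rs))) + 1
    pred = coefs[0] * m[:, 0] + coefs[1] if best == 1 else coefs[2] * m[:, 1] + coefs[3]
    ve = 1.0 - np.var(e - pred) / np.var(e)
    return PositionCalibration(
        model="one_channel", coefficients=np.array(coefs),
        best_channel=best, r_per_channel=(rs[0], rs[1]),
        variance_explained=float(ve),
    )


def _contiguous_folds(n: int, n_folds: int):
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    for i in range(n_folds):
        yield np.arange(bounds[i], bounds[i + 1])


def _ridge_cv(X: np.ndarray, y: np.ndarray, lambda_grid, n_folds: int):
    """Blocked-CV ridge on standardized regressors.

    Returns (coefficients on original scale incl. intercept last, lambda*,
    variance explained on the full data).  Folds are contiguous time blocks
    so that temporal autocorrelation does not leak across folds.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    n = y.size
    errs = np.zeros(grid.size)
    for lo_idx in _contiguous_folds(n, n_folds):
        hi_idx = np.setdiff1d(np.arange(n), lo_idx, assume_unique=True)
        for gi, lam in enumerate(grid):
            model = Ridge(alpha=lam).fit(Z[hi_idx], y[hi_idx])
            resid = y[lo_idx] - model.predict(Z[lo_idx])
            errs[gi] += np.sum(resid**2)
    lam_star = float(grid[int(np.argmin(errs))])
    final = Ridge(alpha=lam_star).fit(Z, y)
    w = final.coef_ / sd
    intercept = final.intercept_ - np.dot(final.coef_, mu / sd)
    pred = X @ w + intercept
    ve = 1.0 - np.var(y - pred) / np.var(y)
    return np.append(w, intercept), lam_star, float(ve)


def fit_position_two_channel(session: AlignedSession,
                             mask: ExclusionMask | None = None,
                             lambda_grid=DEFAULT_LAMBDA_GRID,
                             n_folds: int = 10,
                             seed: int | None = None) -> PositionCalibration:
    """Ridge fit of e(t) = k1*m1 + k2*m2 + k3 with blocked 10-fold CV.

    The penalty minimizing held-out squared error is selected, then the
    regression is rerun on all calibration data at that penalty.  ``seed``
    is accepted for interface symmetry; contiguous-block folds are
    deterministic.
    """
    e, m = _masked(session, mask)
    if e.size <= 100:
        raise ValueError(f"too few included samples ({e.size}) for calibration")
    coefs, lam, ve = _ridge_cv(m, e, lambda_grid, n_folds)
    return PositionCalibration(model="two_channel", coefficients=coefs,
                               ridge_lambda=lam, variance_explained=ve)


def fit_position_quadratic(session: AlignedSession,
                           mask: ExclusionMask | None = None,
                           lambda_grid=DEFAULT_LAMBDA_GRID,
                           n_folds: int = 10,
                           seed: int | None = None) -> PositionCalibration:
    """Ridge fit with quadratic terms: e = k1*m1 + k2*m2 + k3*m1^2 + k4*m2^2 + k5."""
    e, m = _masked(session, mask)
    if e.size <= 100:
        raise ValueError(f"too few included samples ({e.size}) for calibration")
    X = np.column_stack([m[:, 0], m[:, 1], m[:, 0] ** 2, m[:, 1] ** 2])
    coefs, lam, ve = _ridge_cv(X, e, lambda_grid, n_folds)
    return PositionCalibration(model="quadratic", coefficients=coefs,
                               ridge_lambda=lam, variance_explained=ve)


def _sine_fit(t: np.ndarray, y: np.ndarray, f_hz: float):
    """Amplitude, phase (deg) and r^2 of a sin/cos + DC least-squares fit."""
    w = 2.0 * np.pi * f_hz
    X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, _c = beta
    amp = float(np.hypot(a, b))
    phase = float(np.rad2deg(np.arctan2(b, a)))
    pred = X @ beta
    ss = np.var(y)
    r2 = 1.0 - np.var(y - pred) / ss if ss > 0 else 0.0
    return amp, phase, float(r2)


def fit_velocity_calibration(
    video_eye: EyeTrace,
    sensor: SensorTrace,
    stimulus_frequency_hz: float,
    window_ms: float = 50.0,
    video_threshold_deg_s: float = 50.0,
    sensor_threshold_mV_ms: float = 5.0,
    pad_ms: float = 50.0,
    min_r2: float = 0.1,
) -> VelocityCalibration:
    """Amplitude-ratio (velocity) calibration, alignment-free.

    The video-derived eye position is first upsampled (linear interpolation
    on its own clock) to the sensor sample rate, so that the 50 ms
    sliding-window differentiation has the same frequency response on both
    streams and its attenuation cancels in the amplitude ratio.  Both
    velocity traces are desaccaded at the standard thresholds and fitted
    with a sine at the stimulus frequency; the factor is ``A_vid / A_mag``
    (deg/mV) using the sensor channel with the higher sine-fit r^2.  Since
    only the fitted amplitudes enter, a pure time shift between the streams
    does not change the result.
    """
    if video_eye.sample_rate_hz < sensor.sample_rate_hz:
        t_up = np.arange(video_eye.time_s[0], video_eye.time_s[-1],
                         1.0 / sensor.sample_rate_hz)
        keep = np.isfinite(video_eye.position_deg)
        pos_up = np.interp(t_up, video_eye.time_s[keep],
                           video_eye.position_deg[keep])
        video_eye = EyeTrace(t_up, pos_up, sensor.sample_rate_hz)
    ev = differentiate(video_eye, window_ms)
    mv = differentiate(sensor, window_ms)
    vmask = detect_artifacts(ev, video_threshold_deg_s, pad_ms, source="video")
    smask = detect_artifacts(mv, sensor_threshold_mV_ms * 1000.0, pad_ms, source="sensor")

    vk = vmask.included & np.isfinite(ev.value)
    a_vid, _, r2_vid = _sine_fit(ev.time_s[vk], ev.value[vk], stimulus_frequency_hz)

    sk = smask.included
    fits = [
        _sine_fit(mv.time_s[sk], mv.value[sk, c], stimulus_frequency_hz)
        for c in range(2)
    ]
    r2s = (fits[0][2], fits[1][2])
    chosen = int(np.argmax(r2s)) + 1
    a_mag = fits[chosen - 1][0]
    if max(r2s) < min_r2 or r2_vid < min_r2:
        raise ValueError(
            f"sine fits too poor for velocity calibration (video r2={r2_vid:.3f}, "
            f"sensor r2={max(r2s):.3f})")
    return VelocityCalibration(
        a_vid_deg_s=a_vid, a_mag_mV_s=a_mag, chosen_channel=chosen,
        r2_per_channel=r2s, r2_video=r2_vid,
    )


def apply_calibration(trace, calibration) -> np.ndarray:
    """Map a sensor (or sensor-velocity) trace through a fitted calibration.

    * :class:`PositionCalibration` + :class:`SensorTrace` (or (n,2) array)
      -> eye position (deg);
    * :class:`VelocityCalibration` + :class:`VelocityTrace` in mV/s (or an
      array of the chosen channel) -> eye velocity (deg/s).
    """
    if isinstance(calibration, PositionCalibration):
        m = trace.v_mV if isinstance(trace, SensorTrace) else np.asarray(trace, float)
        if m.ndim != 2 or m.shape[1] != 2:
            raise ValueError("position calibration expects a two-channel trace")
        k = calibration.coefficients
        if calibration.model == "one_channel":
            c = calibration.best_channel - 1
            return k[2 * c] * m[:, c] + k[2 * c + 1]
        if calibration.model == "two_channel":
            return k[0] * m[:, 0] + k[1] * m[:, 1] + k[2]
        return (k[0] * m[:, 0] + k[1] * m[:, 1]
                + k[2] * m[:, 0] ** 2 + k[3] * m[:, 1] ** 2 + k[4])
    if isinstance(calibration, VelocityCalibration):
        if isinstance(trace, VelocityTrace):
            if "mV" not in trace.units:
                raise ValueError("velocity calibration expects a sensor-velocity trace (mV/s)")
            v = trace.value
            if v.ndim == 2:
                v = v[:, calibration.chosen_channel - 1]
        else:
            v = np.asarray(trace, dtype=float)
            if v.ndim == 2:
                v = v[:, calibration.chosen_channel - 1]
        return calibration.factor_deg_per_mV * v
    raise TypeError(f"unsupported calibration type {type(calibration)!r}")


def calibration_drift(k_series) -> CalibrationDrift:
    """Percent drift of the calibration factor from day 1.

    dk_n = |k_n - k_1| / k_1 * 100, so dk_1 = 0 by construction.
    """
    k = np.asarray(k_series, dtype=float)
    if k.size == 0:
        raise ValueError("empty calibration series")
    if k[0] == 0:
        raise ValueError("day-1 calibration factor is zero")
    delta = np.abs(k - k[0]) / abs(k[0]) * 100.0
    return CalibrationDrift(k_series=k, delta_pct_series=delta)
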