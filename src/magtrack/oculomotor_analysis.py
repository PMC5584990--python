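"""Oculomotor behavioral metrics.

Gain and phase of sinusoidal VOR/OKR responses, spatial resolution of a
tracker at fixation, body-motion indexing of overhead video with
Active/Still tertile labels, binocular coordination summaries, and the
eye-head velocity relation in freely moving animals.

Phase convention: 0 deg means perfectly compensatory (eye velocity exactly
antiphase to stimulus velocity); positive values are phase leads.  Gain is
the sinusoidal-fit amplitude of the desaccaded eye velocity divided by the
stimulus peak velocity (10 deg/s nominal by default; a fitted stimulus
amplitude can be used instead, e.g. when both traces went through the same
differentiation window and its attenuation should cancel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EyeTrace, ExclusionMask, StimulusTrace, VelocityTrace
from .signal_processing import differentiate

__all__ = [
    "GainPhase",
    "MotionIndexTrace",
    "BinocularSummary",
    "fit_sine",
    "gain_phase",
    "spatial_resolution",
    "motion_index",
    "binocular_stats",
    "eye_head_relation",
]


@dataclass
class GainPhase:
    frequency_hz: float
    gain: float
    phase_deg: float  # relative to ideal compensatory, wrapped to (-180, 180]
    fit_r2: float

    def __post_init__(self):
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if not -180.0 < self.phase_deg <= 180.0:
            raise ValueError("phase must be wrapped to (-180, 180]")


@dataclass
class MotionIndexTrace:
    """Raw and smoothed body-motion index with Active/Middle/Still labels."""

    time_s: np.ndarray
    raw_motion: np.ndarray
    smoothed_motion: np.ndarray
    label: np.ndarray  # "Active" | "Middle" | "Still" per sample


@dataclass
class BinocularSummary:
    """Eye-averaged position/speed statistics and divergence, per condition.

    Keys of the per-condition dicts are "all" and, when motion labels are
    supplied, "Active" and "Still".  Position SD and mean speed are averaged
    across the two eyes before reporting; divergence = right - left angle in
    a common rightward-positive convention.
    """

    position_sd_deg: dict
    mean_speed_deg_s: dict
    divergence_mean_deg: dict
    divergence_sd_deg: dict


def fit_sine(time_s, values, frequency_hz: float,
             mask: ExclusionMask | None = None) -> tuple[float, float, float]:
    """Least-squares sinusoid at a known frequency: (amplitude, phase_deg, r2).

    Fits ``a*sin(wt) + b*cos(wt) + c`` on the included samples (works on
    gappy/masked data since the basis is evaluated at the retained times).
    Amplitude is non-negative; the phase (of ``A*sin(wt + phi)``) absorbs
    the sign.  Requires at least two stimulus cycles of data.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(y)
    if mask is not None:
        keep &= mask.included
    t, y = t[keep], y[keep]
    if t.size < 4 or (t.max() - t.min()) < 2.0 / frequency_hz:
        raise ValueError("need at least two stimulus cycles of included data")
    w = 2.0 * np.pi * frequency_hz
    X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    amp = float(np.hypot(beta[0], beta[1]))
    phase = float(np.rad2deg(np.arctan2(beta[1], beta[0])))
    var = np.var(y)
    r2 = float(1.0 - np.var(y - X @ beta) / var) if var > 0 else 0.0
    return amp, phase, r2


def _wrap_deg(x: float) -> float:
    w = (x + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def gain_phase(eye_velocity: VelocityTrace, stimulus: StimulusTrace,
               mask: ExclusionMask | None = None,
               stimulus_amplitude: str | float = "nominal") -> GainPhase:
    """Gain and phase of the eye-velocity response to a sinusoidal stimulus.

    gain = (eye-velocity sine amplitude) / (stimulus amplitude); the
    stimulus amplitude is the nominal peak velocity by default, or the
    fitted amplitude of ``stimulus.velocity_deg_s`` with
    ``stimulus_amplitude="fitted"``, or an explicit number.  phase =
    eye phase - (stimulus phase + 180 deg), wrapped: 0 deg is perfectly
    compensatory and positive is a lead.
    """
    amp_e, ph_e, r2 = fit_sine(eye_velocity.time_s, eye_velocity.value,
                               stimulus.frequency_hz, mask)
    _, ph_s, _ = fit_sine(stimulus.time_s, stimulus.velocity_deg_s,
                          stimulus.frequency_hz)
    if stimulus_amplitude == "nominal":
        amp_s = stimulus.peak_velocity_deg_s
    elif stimulus_amplitude == "fitted":
        amp_s, _, _ = fit_sine(stimulus.time_s, stimulus.velocity_deg_s,
                               stimulus.frequency_hz)
    else:
        amp_s = float(stimulus_amplitude)
    return GainPhase(frequency_hz=stimulus.frequency_hz, gain=amp_e / amp_s,
                     phase_deg=_wrap_deg(ph_e - (ph_s + 180.0)), fit_r2=r2)


def spatial_resolution(eye: EyeTrace, n_epochs: int = 3, epoch_s: float = 2.0,
                       stationary_velocity_deg_s: float = 0.5,
                       velocity_window_ms: float = 50.0) -> float:
    """Tracker resolution (deg) from stationary fixation epochs.

    Scans disjoint ``epoch_s`` windows, keeps those whose sliding-window
    velocity stays below ``stationary_velocity_deg_s`` in absolute value,
    ranks them by within-window velocity range, and averages the position
    SD (after removing each window's mean) of the ``n_epochs`` quietest.
    Raises (reporting the usable count) when too few epochs qualify.
    """
    vel = differentiate(eye, velocity_window_ms).value
    n_win = int(round(epoch_s * eye.sample_rate_hz))
    if n_win < 2:
        raise ValueError("epoch too short for the sample rate")
    n_total = len(eye) // n_win
    usable = []
    for i in range(n_total):
        sl = slice(i * n_win, (i + 1) * n_win)
        v = vel[sl]
        if np.max(np.abs(v)) < stationary_velocity_deg_s:
            usable.append((float(np.ptp(v)), sl))
    if len(usable) < n_epochs:
        raise ValueError(
            f"only {len(usable)} stationary epochs available, need {n_epochs}")
    usable.sort(key=lambda u: u[0])
    sds = [float(np.std(eye.position_deg[sl] - eye.position_deg[sl].mean()))
           for _, sl in usable[:n_epochs]]
    return float(np.mean(sds))


def motion_index(frames: np.ndarray, frame_rate_hz: float = 30.0,
                 smooth_s: float = 2.0) -> MotionIndexTrace:
    """Body-motion index from overhead video, with Active/Still tertiles.

    Subtracts the pixel-wise mean background, takes the mean absolute
    difference between consecutive frames, smooths with a centered
    ``smooth_s`` moving average, and labels the upper third of smoothed
    values "Active", the lower third "Still", the rest "Middle".  Ties are
    broken by stable value rank, so label counts differ from n/3 by at
    most 1 for distinct values.
    """
    f = np.asarray(frames, dtype=float)
    if f.ndim != 3 or f.shape[0] < 2:
        raise ValueError("need at least two frames of constant size")
    bg = f.mean(axis=0)
    resid = f - bg
    raw = np.abs(np.diff(resid, axis=0)).mean(axis=(1, 2))
    n = raw.size
    win = min(max(1, int(round(smooth_s * frame_rate_hz))), n)
    kernel = np.ones(win) / win
    # centered moving average with edge renormalization
    smoothed = np.convolve(raw, kernel, mode="same")
    norm = np.convolve(np.ones(n), kernel, mode="same")
    smoothed = smoothed / norm
    order = np.argsort(smoothed, kind="stable")
    label = np.empty(n, dtype=object)
    third = n // 3
    n_active = n - 2 * third - (1 if n % 3 == 2 else 0)
    label[order[:third]] = "Still"
    label[order[third:n - n_active]] = "Middle"
    label[order[n - n_active:]] = "Active"
    t = (np.arange(n) + 0.5) / frame_rate_hz
    return MotionIndexTrace(time_s=t, raw_motion=raw, smoothed_motion=smoothed,
                            label=label.astype(str))


def _condition_slices(labels: np.ndarray | None):
    conds = {"all": slice(None)}
    if labels is not None:
        conds["Active"] = labels == "Active"
        conds["Still"] = labels == "Still"
    return conds


def binocular_stats(left: EyeTrace, right: EyeTrace,
                    labels: MotionIndexTrace | None = None,
                    velocity_window_ms: float = 50.0) -> BinocularSummary:
    """Binocular position/speed statistics and divergence.

    Both traces must share one timeline and a common rightward-positive
    convention.  Per-eye position SD and mean absolute velocity are
    averaged across the two eyes before reporting; divergence is
    right - left.  When a motion-index trace is supplied its per-frame
    labels are resampled (nearest) onto the eye timeline to split the
    statistics into Active/Still conditions.
    """
    if len(left) != len(right) or not np.allclose(left.time_s, right.time_s):
        raise ValueError("eye traces must share one timeline")
    vl = differentiate(left, velocity_window_ms).value
    vr = differentiate(right, velocity_window_ms).value
    div = right.position_deg - left.position_deg

    lab = None
    if labels is not None:
        idx = np.clip(np.searchsorted(labels.time_s, left.time_s), 0,
                      labels.label.size - 1)
        lab = labels.label[idx]

    pos_sd, speed, div_mean, div_sd = {}, {}, {}, {}
    for name, sel in _condition_slices(lab).items():
        le, re_ = left.position_deg[sel], right.position_deg[sel]
        if np.size(le) == 0:
            continue
        pos_sd[name] = float((np.std(le) + np.std(re_)) / 2.0)
        speed[name] = float((np.mean(np.abs(vl[sel])) + np.mean(np.abs(vr[sel]))) / 2.0)
        div_mean[name] = float(np.mean(div[sel]))
        div_sd[name] = float(np.std(div[sel]))
    return BinocularSummary(position_sd_deg=pos_sd, mean_speed_deg_s=speed,
                            divergence_mean_deg=div_mean, divergence_sd_deg=div_sd)


def eye_head_relation(eye_velocity, head_yaw_velocity,
                      mask: ExclusionMask | None = None) -> tuple[float, float]:
    """OLS slope and Pearson r of eye velocity on head yaw velocity."""
    e = np.asarray(eye_velocity.value if isinstance(eye_velocity, VelocityTrace)
                   else eye_velocity, dtype=float)
    h = np.asarray(head_yaw_velocity.value if isinstance(head_yaw_velocity, VelocityTrace)
                   else head_yaw_velocity, dtype=float)
    if e.shape != h.shape:
        raise ValueError("traces must be aligned and equal length")
    keep = np.isfinite(e) & np.isfinite(h)
    if mask is not None:
        keep &= mask.included
    e, h = e[keep], h[keep]
    if np.std(h) == 0:
        raise ValueError("head velocity is constant: slope undefined")
    slope = float(np.polyfit(h, e, 1)[0])
    r = float(np.corrcoef(h, e)[0, 1])
    return slope, r
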