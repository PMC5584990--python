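"""Readers/writers for the project's file dialects and the session pipeline.

All time series travel as CSV with a header row whose column suffixes carry
the units (``_s``, ``_deg``, ``_mV``); structured outputs (configs,
calibrations, reports) are JSON.  Data volumes are desk-scale, so the
formats favor diff-ability over compactness.

A session directory, as written by the ``simulate`` CLI subcommand, holds::

    stimulus.csv            time_s, position_deg, velocity_deg_s
    sensor.csv              time_s, ch1_mV, ch2_mV
    ttl.csv                 ttl_time_s (sync-pulse onsets, sensor clock)
    camera_landmarks.csv    time_s, cam, pupil_x_px, pupil_y_px, cr_x_px, cr_y_px, valid
    brightness.csv          frame, mean_intensity (for sync-flash detection)
    truth.json              ground-truth parameters (synthetic sessions)
    config.json             generation parameters and seed

:func:`run_pipeline` ties the stages together: landmarks -> angular eye
position -> sync alignment -> desaccading -> calibration -> application ->
gain/phase analysis, writing ``calibration.json`` and ``report.json``.
Reports embed the config hash and seeds and contain no timestamps, so a
rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import calibration as cal
from . import signal_processing as sp
from .core import EyeTrace, SensorTrace, StimulusTrace
from .oculomotor_analysis import gain_phase, spatial_resolution
from .pupil_detect import detect_sync_flash
from .video_geometry import CameraRig, PupilFrameSeries, eye_position_from_frames

__all__ = [
    "SessionConfig",
    "RigConfig",
    "CalibrationConfig",
    "AnalysisConfig",
    "read_timeseries",
    "write_sensor_trace",
    "read_sensor_trace",
    "write_landmarks",
    "read_landmarks",
    "write_session_dir",
    "run_pipeline",
    "config_hash",
]


# ---------------------------------------------------------------------------
# configuration schema

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RigConfig(_Strict):
    inter_camera_angle_deg: float = 40.0
    camera_distance_mm: float = 50.0
    pixel_scale_mm_per_px: float = 0.005
    frame_rate_hz: float = 30.0
    nasal_camera: int = 2

    def to_rig(self) -> CameraRig:
        return CameraRig(**self.model_dump())


class CalibrationConfig(_Strict):
    method: str = "position"  # position | velocity
    model: str = "one_channel"  # one_channel | two_channel | quadratic
    lambda_min: float = 1e-6
    lambda_max: float = 1e3
    n_lambdas: int = 25
    n_folds: int = 10
    seed: int = 0

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.lambda_min), np.log10(self.lambda_max),
                           self.n_lambdas)


class AnalysisConfig(_Strict):
    window_ms: float = 50.0
    video_threshold_deg_s: float = 50.0
    sensor_threshold_mV_ms: float = 5.0
    pad_ms: float = 50.0
    stationary_velocity_deg_s: float = 0.5
    stimulus_amplitude: str = "nominal"  # nominal | fitted


class SessionConfig(_Strict):
    session_dir: str
    output_dir: str
    stimulus_frequency_hz: float = 1.0
    rig: RigConfig = RigConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int = 0


def config_hash(config: SessionConfig) -> str:
    """Hash of the scientific parameters (paths excluded)."""
    dump = config.model_dump(exclude={"session_dir", "output_dir"})
    payload = json.dumps(dump, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# CSV dialects

_UNIT_SUFFIXES = ("_s", "_deg", "_mV", "_px", "_deg_s")


def read_timeseries(path, rtol: float = 1e-6):
    """Read a CSV time series, dispatching on its columns.

    ``time_s, ch1_mV, ch2_mV`` -> :class:`SensorTrace`;
    ``time_s, eye_deg`` (or any single ``*_deg``) -> :class:`EyeTrace`;
    ``time_s, position_deg, velocity_deg_s`` needs the stimulus frequency
    and is read by :func:`read_stimulus`.  The time column must be strictly
    increasing and uniform within ``rtol``; units are taken from the header
    suffixes and must be present.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing 'time_s' column (units suffix required)")
    for col in df.columns:
        if not col.endswith(_UNIT_SUFFIXES) and col != "time_s":
            raise ValueError(f"{path}: column {col!r} lacks a units suffix")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if t.size >= 2:
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time column must be strictly increasing")
        if np.ptp(dt) > rtol * np.median(dt) + 1e-12:
            raise ValueError(f"{path}: sampling is not uniform within tolerance")
    rate = 1.0 / float(np.median(dt)) if t.size >= 2 else 1.0
    if {"ch1_mV", "ch2_mV"} <= set(df.columns):
        v = df[["ch1_mV", "ch2_mV"]].to_numpy(float)
        return SensorTrace(time_s=t, v_mV=v, sample_rate_hz=rate)
    deg_cols = [c for c in df.columns if c.endswith("_deg")]
    if len(deg_cols) == 1:
        return EyeTrace(time_s=t, position_deg=df[deg_cols[0]].to_numpy(float),
                        sample_rate_hz=rate)
    raise ValueError(f"{path}: unrecognized column set {list(df.columns)}")


def write_eye_trace(path, eye: EyeTrace, column: str = "eye_deg") -> None:
    pd.DataFrame({"time_s": eye.time_s, column: eye.position_deg}).to_csv(
        path, index=False)


def write_sensor_trace(dirpath, sensor: SensorTrace, metadata: dict | None = None,
                       stem: str = "sensor") -> None:
    """Write a sensor trace as CSV + TTL CSV + JSON metadata sidecar."""
    d = Path(dirpath)
    pd.DataFrame({"time_s": sensor.time_s, "ch1_mV": sensor.v_mV[:, 0],
                  "ch2_mV": sensor.v_mV[:, 1]}).to_csv(d / f"{stem}.csv", index=False)
    if sensor.ttl_pulse_times_s is not None:
        pd.DataFrame({"ttl_time_s": sensor.ttl_pulse_times_s}).to_csv(
            d / "ttl.csv", index=False)
    if metadata is not None:
        meta = dict(metadata)
        meta["sample_rate_hz"] = sensor.sample_rate_hz
        (d / f"{stem}.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_sensor_trace(dirpath, stem: str = "sensor") -> SensorTrace:
    d = Path(dirpath)
    trace = read_timeseries(d / f"{stem}.csv")
    ttl_path = d / "ttl.csv"
    if ttl_path.exists():
        ttl = pd.read_csv(ttl_path)["ttl_time_s"].to_numpy(float)
        trace = SensorTrace(time_s=trace.time_s, v_mV=trace.v_mV,
                            sample_rate_hz=trace.sample_rate_hz,
                            ttl_pulse_times_s=ttl)
    return trace


def read_stimulus(path, frequency_hz: float,
                  peak_velocity_deg_s: float | None = None) -> StimulusTrace:
    df = pd.read_csv(path)
    vel = df["velocity_deg_s"].to_numpy(float)
    peak = peak_velocity_deg_s if peak_velocity_deg_s is not None else float(
        np.max(np.abs(vel)))
    return StimulusTrace(time_s=df["time_s"].to_numpy(float),
                         position_deg=df["position_deg"].to_numpy(float),
                         velocity_deg_s=vel, frequency_hz=frequency_hz,
                         peak_velocity_deg_s=peak)


def write_landmarks(path, frames: PupilFrameSeries) -> None:
    """Landmark CSV, long format: one row per (frame, camera)."""
    n = len(frames)
    rows = {
        "time_s": np.repeat(frames.time_s, 2),
        "cam": np.tile([1, 2], n),
        "pupil_x_px": frames.pupil_px[:, :, 0].ravel(),
        "pupil_y_px": frames.pupil_px[:, :, 1].ravel(),
        "cr_x_px": frames.cr_px[:, :, 0].ravel(),
        "cr_y_px": frames.cr_px[:, :, 1].ravel(),
        "valid": np.repeat(frames.valid.astype(int), 2),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path, pixel_scale_mm_per_px: float) -> PupilFrameSeries:
    df = pd.read_csv(path)
    t = np.unique(df["time_s"].to_numpy(float))
    n = t.size
    pupil = np.full((n, 2, 2), np.nan)
    crp = np.full((n, 2, 2), np.nan)
    valid = np.ones(n, dtype=bool)
    pos = {tv: i for i, tv in enumerate(t)}
    for _, row in df.iterrows():
        i, c = pos[row["time_s"]], int(row["cam"]) - 1
        pupil[i, c] = (row["pupil_x_px"], row["pupil_y_px"])
        crp[i, c] = (row["cr_x_px"], row["cr_y_px"])
        valid[i] &= bool(row["valid"])
    valid &= np.isfinite(pupil).all(axis=(1, 2)) & np.isfinite(crp).all(axis=(1, 2))
    pupil = np.nan_to_num(pupil)
    crp = np.nan_to_num(crp)
    return PupilFrameSeries(time_s=t, pupil_px=pupil, cr_px=crp,
                            pixel_scale_mm_per_px=pixel_scale_mm_per_px, valid=valid)


def write_masks(path, intervals: list[tuple[float, float]], source: str) -> None:
    pd.DataFrame({"start_s": [s for s, _ in intervals],
                  "end_s": [e for _, e in intervals],
                  "source": source}).to_csv(path, index=False)


def save_calibration(path, calibration, extra: dict | None = None) -> None:
    if isinstance(calibration, cal.PositionCalibration):
        payload = {
            "type": "position", "model": calibration.model,
            "coefficients": calibration.coefficients.tolist(),
            "ridge_lambda": calibration.ridge_lambda,
            "best_channel": calibration.best_channel,
            "r_per_channel": calibration.r_per_channel,
            "variance_explained": calibration.variance_explained,
            "k_deg_per_mV": calibration.k,
        }
    elif isinstance(calibration, cal.VelocityCalibration):
        payload = {
            "type": "velocity",
            "a_vid_deg_s": calibration.a_vid_deg_s,
            "a_mag_mV_s": calibration.a_mag_mV_s,
            "chosen_channel": calibration.chosen_channel,
            "r2_per_channel": list(calibration.r2_per_channel),
            "k_deg_per_mV": calibration.factor_deg_per_mV,
        }
    else:
        raise TypeError(f"unsupported calibration {type(calibration)!r}")
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_calibration(path):
    payload = json.loads(Path(path).read_text())
    if payload["type"] == "position":
        return cal.PositionCalibration(
            model=payload["model"],
            coefficients=np.asarray(payload["coefficients"]),
            ridge_lambda=payload.get("ridge_lambda"),
            best_channel=payload.get("best_channel"),
            r_per_channel=tuple(payload["r_per_channel"]) if payload.get("r_per_channel") else None,
            variance_explained=payload.get("variance_explained", 0.0),
        )
    return cal.VelocityCalibration(
        a_vid_deg_s=payload["a_vid_deg_s"], a_mag_mV_s=payload["a_mag_mV_s"],
        chosen_channel=payload["chosen_channel"],
        r2_per_channel=tuple(payload["r2_per_channel"]),
    )


def write_session_dir(dirpath, bundle, render_frames: int = 0) -> None:
    """Write a synthetic session bundle as a session directory."""
    from .synthetic_data import render_eye_frames  # local: optional heavy dep path

    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": bundle.stimulus.time_s,
                  "position_deg": bundle.stimulus.position_deg,
                  "velocity_deg_s": bundle.stimulus.velocity_deg_s}).to_csv(
        d / "stimulus.csv", index=False)
    write_sensor_trace(d, bundle.sensor, metadata={"seed": bundle.seed})
    write_landmarks(d / "camera_landmarks.csv", bundle.camera)
    pd.DataFrame({"frame": np.arange(bundle.camera_brightness.size),
                  "mean_intensity": bundle.camera_brightness}).to_csv(
        d / "brightness.csv", index=False)
    truth = {
        "k_true_deg_per_mV": bundle.k_true_deg_per_mV,
        "response_gain": bundle.kinematics.response_gain,
        "response_phase_deg": bundle.kinematics.response_phase_deg,
        "camera_latency_s": bundle.camera_latency_s,
        "clock_drift": bundle.clock_drift,
        "seed": bundle.seed,
    }
    (d / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    cfg = {
        "frequency_hz": bundle.stimulus.frequency_hz,
        "peak_velocity_deg_s": bundle.stimulus.peak_velocity_deg_s,
        "sample_rate_hz": bundle.kinematics.sample_rate_hz,
        "pixel_scale_mm_per_px": bundle.rig.pixel_scale_mm_per_px,
        "seed": bundle.seed,
    }
    (d / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
    if render_frames:
        import imageio.v3 as iio

        fdir = d / "frames"
        fdir.mkdir(exist_ok=True)
        idx = np.arange(min(render_frames, len(bundle.camera)))
        imgs = render_eye_frames(bundle.camera, seed=bundle.seed, indices=idx)
        for row, i in enumerate(idx):
            for cam in range(2):
                iio.imwrite(fdir / f"cam{cam + 1}_{i:06d}.png", imgs[row, cam])


def run_pipeline(config: SessionConfig) -> dict:
    """Execute the full session pipeline and write calibration + report.

    Stages: read landmarks -> angular eye position -> sync-flash alignment
    -> differentiation and velocity-threshold desaccading -> calibration
    (per config) -> apply to the sensor trace -> gain/phase analysis.
    Deterministic given identical inputs, config and seeds; every stage
    failure is re-raised tagged with the stage name.
    """
    session = Path(config.session_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config_hash(config), "seed": config.seed,
                    "stages": {}}
    rig = config.rig.to_rig()
    acfg = config.analysis

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # tag and halt
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    frames = stage("landmarks")(lambda: read_landmarks(
        session / "camera_landmarks.csv", rig.pixel_scale_mm_per_px))
    sensor = stage("sensor")(lambda: read_sensor_trace(session))
    stimulus = stage("stimulus")(lambda: read_stimulus(
        session / "stimulus.csv", config.stimulus_frequency_hz))
    report["stages"]["inputs"] = {"n_frames": len(frames), "n_sensor": len(sensor)}

    video_eye = stage("geometry")(lambda: eye_position_from_frames(frames, rig))

    brightness = pd.read_csv(session / "brightness.csv")["mean_intensity"].to_numpy()
    flash_idx = stage("sync")(lambda: detect_sync_flash(brightness))

    ev = sp.differentiate(video_eye, acfg.window_ms)
    vmask = sp.detect_artifacts(ev, acfg.video_threshold_deg_s, acfg.pad_ms, "video")
    mv = sp.differentiate(sensor, acfg.window_ms)
    smask = sp.detect_artifacts(mv, acfg.sensor_threshold_mV_ms * 1000.0,
                                acfg.pad_ms, "sensor")
    aligned = stage("align")(lambda: sp.align_streams(
        video_eye, flash_idx, sensor, video_mask=vmask, sensor_mask=smask))
    report["stages"]["align"] = {
        "clock_offset_s": aligned.clock_offset_s,
        "clock_drift": aligned.clock_drift,
        "n_flashes": int(len(flash_idx)),
        "excluded_fraction": float(aligned.excluded.mean()),
    }
    write_masks(out / "masks.csv",
                sp.ExclusionMask(aligned.excluded, "union").intervals_s(aligned.time_s),
                "union")

    ccfg = config.calibration
    if ccfg.method == "velocity":
        fitted = stage("calibrate")(lambda: cal.fit_velocity_calibration(
            video_eye, sensor, config.stimulus_frequency_hz,
            window_ms=acfg.window_ms,
            video_threshold_deg_s=acfg.video_threshold_deg_s,
            sensor_threshold_mV_ms=acfg.sensor_threshold_mV_ms,
            pad_ms=acfg.pad_ms))
    else:
        fitters = {"one_channel": cal.fit_position_one_channel}
        if ccfg.model in ("two_channel", "quadratic"):
            fn = (cal.fit_position_two_channel if ccfg.model == "two_channel"
                  else cal.fit_position_quadratic)
            fitted = stage("calibrate")(lambda: fn(
                aligned, lambda_grid=ccfg.lambda_grid, n_folds=ccfg.n_folds,
                seed=ccfg.seed))
        else:
            fitted = stage("calibrate")(lambda: fitters[ccfg.model](aligned))
    save_calibration(out / "calibration.json", fitted,
                     extra={"config_hash": report["config_hash"]})
    report["stages"]["calibration"] = json.loads(
        (out / "calibration.json").read_text())

    # apply to the sensor stream and measure the oculomotor response
    if isinstance(fitted, cal.VelocityCalibration):
        eye_vel_value = cal.apply_calibration(mv, fitted)
    else:
        eye_hat = cal.apply_calibration(sensor, fitted)
        eye_vel_value = sp.differentiate(
            EyeTrace(sensor.time_s, eye_hat, sensor.sample_rate_hz),
            acfg.window_ms).value
    eye_vel = sp.VelocityTrace(time_s=sensor.time_s, value=eye_vel_value,
                               units="deg/s", window_ms=acfg.window_ms)
    vel_mask = sp.detect_artifacts(eye_vel, acfg.video_threshold_deg_s,
                                   acfg.pad_ms, "sensor")
    gp = stage("analyze")(lambda: gain_phase(
        eye_vel, stimulus, mask=vel_mask,
        stimulus_amplitude=acfg.stimulus_amplitude))
    report["stages"]["analysis"] = {
        "frequency_hz": gp.frequency_hz, "gain": gp.gain,
        "phase_deg": gp.phase_deg, "fit_r2": gp.fit_r2,
        "phase_convention": "0 deg = compensatory; positive = lead",
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
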