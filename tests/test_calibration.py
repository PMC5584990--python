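"""Voltage-to-angle calibration: position regressions, velocity ratio, drift."""

import numpy as np
import pytest

from magtrack.calibration import (
    DEFAULT_LAMBDA_GRID,
    PositionCalibration,
    apply_calibration,
    calibration_drift,
    fit_position_one_channel,
    fit_position_quadratic,
    fit_position_two_channel,
    fit_velocity_calibration,
)
from magtrack.core import EyeTrace, SensorTrace
from magtrack.signal_processing import AlignedSession
from magtrack.video_geometry import eye_position_from_frames


def make_session(e, m, fs=1000.0):
    t = np.arange(e.size) / fs
    return AlignedSession(time_s=t, eye_deg=e, v_mV=m,
                          excluded=np.zeros(e.size, bool), sample_rate_hz=fs,
                          clock_offset_s=0.0, clock_drift=0.0,
                          flash_residuals_s=np.zeros(2))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


class TestOneChannel:
    def test_exact_affine_recovery(self, rng):
        m1 = rng.normal(0, 200, 5000)
        m = np.column_stack([m1, rng.normal(0, 200, 5000)])
        e = 0.005 * m1 + 1.0
        cal = fit_position_one_channel(make_session(e, m))
        assert cal.best_channel == 1
        assert cal.coefficients[0] == pytest.approx(0.005, rel=1e-9)
        assert cal.coefficients[1] == pytest.approx(1.0, rel=1e-9)
        assert cal.r_per_channel[0] == pytest.approx(1.0, abs=1e-12)

    def test_informative_channel_selected(self, rng):
        e = rng.normal(0, 2, 5000)
        m = np.column_stack([e / 0.005 + rng.normal(0, 10, 5000),
                             rng.normal(0, 200, 5000)])
        cal = fit_position_one_channel(make_session(e, m))
        assert cal.best_channel == 1

    def test_negative_polarity_selected_by_abs_r(self, rng):
        e = rng.normal(0, 2, 5000)
        m = np.column_stack([rng.normal(0, 200, 5000), -e / 0.005])
        cal = fit_position_one_channel(make_session(e, m))
        assert cal.best_channel == 2
        assert cal.k == pytest.approx(-0.005, rel=1e-9)

    def test_uncorrelated_noise_flagged_low_quality(self, rng):
        e = rng.normal(0, 2, 5000)
        m = rng.normal(0, 200, (5000, 2))
        cal = fit_position_one_channel(make_session(e, m))
        assert max(abs(r) for r in cal.r_per_channel) < 0.1
        assert cal.variance_explained < 0.05

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_position_one_channel(make_session(np.zeros(50), np.zeros((50, 2))))


class TestTwoChannelRidge:
    def test_ols_limit_recovers_coefficients(self, rng):
        m1 = rng.normal(0, 5, 4000)
        m = np.column_stack([m1, rng.normal(0, 5, 4000)])
        e = 2.0 * m1 + 3.0
        cal = fit_position_two_channel(make_session(e, m))
        assert cal.coefficients[0] == pytest.approx(2.0, rel=0.01)
        assert cal.coefficients[2] == pytest.approx(3.0, rel=0.01)
        assert cal.variance_explained > 0.999

    def test_collinear_channels_handled(self, rng):
        m1 = rng.normal(0, 100, 4000)
        m = np.column_stack([m1, m1 + rng.normal(0, 1e-3, 4000)])
        e = 0.004 * m1 + rng.normal(0, 0.05, 4000)
        cal2 = fit_position_two_channel(make_session(e, m))
        cal1 = fit_position_one_channel(make_session(e, m))
        assert np.all(np.isfinite(cal2.coefficients))
        assert cal2.variance_explained == pytest.approx(
            cal1.variance_explained, abs=0.01)

    def test_empty_lambda_grid_rejected(self, rng):
        e = rng.normal(0, 1, 2000)
        m = rng.normal(0, 1, (2000, 2))
        with pytest.raises(ValueError):
            fit_position_two_channel(make_session(e, m), lambda_grid=[])

    def test_lambda_selection_reproducible(self, rng):
        m = rng.normal(0, 100, (3000, 2))
        e = 0.005 * m[:, 0] + 0.002 * m[:, 1] + rng.normal(0, 0.1, 3000)
        s = make_session(e, m)
        lams = {fit_position_two_channel(s).ridge_lambda for _ in range(3)}
        assert len(lams) == 1


class TestQuadratic:
    def test_pure_quadratic_captured_only_by_quadratic_model(self, rng):
        m1 = np.linspace(-300, 300, 4000)
        m = np.column_stack([m1, rng.normal(0, 5, 4000)])
        e = 0.001 * m1**2
        s = make_session(e, m)
        quad = fit_position_quadratic(s)
        lin = fit_position_two_channel(s)
        assert quad.variance_explained > 0.999
        assert lin.variance_explained < 0.9

    def test_linear_truth_gives_near_zero_quadratic_terms(self, rng):
        m = rng.normal(0, 100, (4000, 2))
        e = 0.005 * m[:, 0] + 0.1
        quad = fit_position_quadratic(make_session(e, m))
        lin = fit_position_two_channel(make_session(e, m))
        assert abs(quad.coefficients[2]) < 1e-6
        assert abs(quad.coefficients[3]) < 1e-6
        assert quad.variance_explained == pytest.approx(lin.variance_explained,
                                                        abs=1e-6)

    def test_model_hierarchy_on_training_data(self, session_bundle):
        from magtrack.signal_processing import align_streams

        b = session_bundle
        video_eye = eye_position_from_frames(b.camera, b.rig)
        s = align_streams(video_eye, b.flash_frame_indices, b.sensor)
        tiny = np.array([1e-8])
        ve1 = fit_position_one_channel(s).variance_explained
        ve2 = fit_position_two_channel(s, lambda_grid=tiny).variance_explained
        ve3 = fit_position_quadratic(s, lambda_grid=tiny).variance_explained
        assert ve3 >= ve2 - 1e-9 >= ve1 - 2e-9


class TestVelocityCalibration:
    def _traces(self, k=0.005, shift_s=0.0, fs=1000.0, dur=20.0):
        t = np.arange(0, dur, 1 / fs)
        e = 10.0 / (2 * np.pi) * np.cos(2 * np.pi * (t - shift_s))
        eye = EyeTrace(t, e, fs)
        m1 = (10.0 / (2 * np.pi)) / k * np.cos(2 * np.pi * t)
        sensor = SensorTrace(t, np.column_stack([m1, np.zeros_like(m1)]), fs)
        return eye, sensor

    def test_amplitude_ratio_recovers_factor(self):
        eye, sensor = self._traces(k=0.005)
        cal = fit_velocity_calibration(eye, sensor, 1.0)
        assert cal.chosen_channel == 1
        assert cal.factor_deg_per_mV == pytest.approx(0.005, rel=1e-6)

    def test_time_shift_invariance(self):
        eye0, sensor = self._traces(k=0.005)
        eye_shift, _ = self._traces(k=0.005, shift_s=0.2)
        k0 = fit_velocity_calibration(eye0, sensor, 1.0).factor_deg_per_mV
        k1 = fit_velocity_calibration(eye_shift, sensor, 1.0).factor_deg_per_mV
        # identical up to finite-trace edge effects of the sliding window
        assert k1 == pytest.approx(k0, rel=1e-4)

    def test_agrees_with_position_method(self, session_bundle):
        from magtrack.signal_processing import align_streams

        b = session_bundle
        video_eye = eye_position_from_frames(b.camera, b.rig)
        aligned = align_streams(video_eye, b.flash_frame_indices, b.sensor)
        k_pos = fit_position_one_channel(aligned).k
        k_vel = fit_velocity_calibration(video_eye, b.sensor, 1.0).factor_deg_per_mV
        assert k_vel == pytest.approx(abs(k_pos), rel=0.02)

    def test_flat_signals_rejected(self):
        t = np.arange(0, 20, 1e-3)
        eye = EyeTrace(t, np.zeros(t.size), 1000.0)
        sensor = SensorTrace(t, np.zeros((t.size, 2)), 1000.0)
        with pytest.raises(ValueError):
            fit_velocity_calibration(eye, sensor, 1.0)


class TestApplyCalibration:
    def test_position_inverse_map_round_trip(self, rng):
        e = rng.normal(0, 2, 1000)
        m1 = (e - 1.0) / 0.005
        m = np.column_stack([m1, np.zeros(1000)])
        cal = PositionCalibration(model="one_channel",
                                  coefficients=[0.005, 1.0, np.nan, np.nan],
                                  best_channel=1)
        assert np.allclose(apply_calibration(m, cal), e, atol=1e-9)

    def test_zero_voltage_returns_offset(self):
        cal = PositionCalibration(model="one_channel",
                                  coefficients=[0.005, 1.5, np.nan, np.nan],
                                  best_channel=1)
        out = apply_calibration(np.zeros((10, 2)), cal)
        assert np.allclose(out, 1.5)

    def test_end_to_end_small_angle_round_trip(self, clean_bundle):
        b = clean_bundle
        cal = PositionCalibration(
            model="one_channel",
            coefficients=[b.k_true_deg_per_mV, 0.0, np.nan, np.nan],
            best_channel=1)
        rec = apply_calibration(b.sensor, cal)
        r = np.corrcoef(rec, b.eye.position_deg)[0, 1]
        assert r**2 > 0.999

    def test_model_mismatch_rejected(self):
        cal = PositionCalibration(model="two_channel", coefficients=[1, 1, 0])
        with pytest.raises(ValueError):
            apply_calibration(np.zeros((5, 3)), cal)


class TestCalibrationDrift:
    def test_twenty_percent_step(self):
        d = calibration_drift([0.010, 0.012])
        assert d.delta_pct_series == pytest.approx([0.0, 20.0])

    def test_constant_series_all_zero(self):
        d = calibration_drift([0.01] * 5)
        assert np.allclose(d.delta_pct_series, 0.0)

    def test_mixed_series(self):
        d = calibration_drift([0.010, 0.008, 0.011])
        assert d.delta_pct_series == pytest.approx([0.0, 20.0, 10.0])

    def test_zero_day1_rejected(self):
        with pytest.raises(ValueError):
            calibration_drift([0.0, 0.01])
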