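"""AMR sensor forward model and sensitivity estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magtrack.core import EyeTrace
from magtrack.sensor_model import (
    MEAN_SLOPE_PER_AMPLITUDE,
    AMRSensorSpec,
    MagnetGeometry,
    amr_response,
    dipole_field_angle,
    estimate_sensitivity,
    sensitivity_profile,
    simulate_sensor_trace,
)
from magtrack.sensor_model import _angle_gain, small_angle_sensitivity


def spec_a1000():
    return AMRSensorSpec(peak_amplitude_mV=1000.0, noise_sd_mV=0.0)


class TestAmrResponse:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (0.0, (0.0, -1000.0)),  # sin(0)=0; sin(-90 deg)=-1
            (22.5, (707.1067812, -707.1067812)),  # sin(+-45 deg) = 1/sqrt(2)
            (45.0, (1000.0, 0.0)),
        ],
    )
    def test_reference_angles(self, theta, expected):
        v = amr_response(theta, spec_a1000())
        assert v == pytest.approx(expected, abs=1e-5)

    def test_half_turn_periodicity(self):
        assert amr_response(30.0, spec_a1000()) == pytest.approx(
            amr_response(210.0, spec_a1000()))

    @given(st.floats(-360, 360))
    @settings(max_examples=50, deadline=None)
    def test_channel2_is_channel1_shifted_45(self, theta):
        spec = spec_a1000()
        v = amr_response(theta, spec)
        v_shift = amr_response(theta - 45.0, spec)
        assert v[1] == pytest.approx(v_shift[0], abs=1e-9)

    def test_offsets_added_per_channel(self):
        spec = AMRSensorSpec(peak_amplitude_mV=1000.0,
                             baseline_offset_mV=(5.0, -3.0), noise_sd_mV=0.0)
        assert amr_response(0.0, spec) == pytest.approx((5.0, -1003.0))

    def test_nonfinite_angle_rejected(self):
        with pytest.raises(ValueError):
            amr_response(np.nan, spec_a1000())

    def test_channel_phases_must_differ_45(self):
        with pytest.raises(ValueError):
            AMRSensorSpec(channel_phase_deg=(0.0, 30.0))


class TestSensitivityProfile:
    def test_reference_geometry_returns_peak_amplitude(self):
        spec = spec_a1000()
        g = MagnetGeometry(vertical_distance_mm=0.0)
        assert sensitivity_profile(g, spec) == pytest.approx(1000.0)

    def test_3mm_anchor_mean_slope_is_127(self):
        # amplitude such that the +-22.5 deg mean slope equals 127.0 mV/deg
        amp = sensitivity_profile(MagnetGeometry(vertical_distance_mm=3.0))
        assert amp * MEAN_SLOPE_PER_AMPLITUDE == pytest.approx(127.0, rel=1e-6)
        assert amp == pytest.approx(127.0 / (np.sqrt(2.0) / 45.0), rel=1e-6)

    def test_monotone_in_vertical_distance(self):
        amps = [sensitivity_profile(MagnetGeometry(vertical_distance_mm=d))
                for d in np.linspace(0, 6, 25)]
        assert all(a >= b - 1e-9 for a, b in zip(amps, amps[1:]))
        a3 = sensitivity_profile(MagnetGeometry(vertical_distance_mm=3.0))
        a5 = sensitivity_profile(MagnetGeometry(vertical_distance_mm=5.0))
        assert a5 < a3

    def test_monotone_in_horizontal_offset(self):
        amps = [sensitivity_profile(
            MagnetGeometry(vertical_distance_mm=3.0, horizontal_offset_mm=dh))
            for dh in np.linspace(0, 5, 21)]
        assert all(a >= b - 1e-9 for a, b in zip(amps, amps[1:]))

    def test_half_maximum_retained_at_eye_radius_offset(self):
        a0 = sensitivity_profile(MagnetGeometry(vertical_distance_mm=3.0))
        a15 = sensitivity_profile(
            MagnetGeometry(vertical_distance_mm=3.0, horizontal_offset_mm=1.5))
        assert 0.5 * a0 < a15 < a0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            MagnetGeometry(vertical_distance_mm=-1.0)


class TestDipoleFieldAngle:
    def test_on_axis_field_antiparallel_to_moment(self):
        g = MagnetGeometry(vertical_distance_mm=3.0)
        assert dipole_field_angle(g, 0.0) == pytest.approx(180.0)

    def test_on_axis_sweep_constant_offset(self):
        g = MagnetGeometry(vertical_distance_mm=3.0)
        theta = np.linspace(-22.5, 22.5, 45)
        diff = (dipole_field_angle(g, theta) - theta) % 360.0
        assert np.allclose(diff, 180.0, atol=1e-9)

    def test_offset_geometry_mean_gain_between_half_and_one(self):
        g = MagnetGeometry(vertical_distance_mm=3.0, horizontal_offset_mm=1.5,
                           lever_arm_mm=1.5)
        gain = _angle_gain(g)
        assert 0.5 < gain < 1.0

    def test_sensor_on_dipole_is_singular(self):
        g = MagnetGeometry(vertical_distance_mm=0.0, horizontal_offset_mm=1.0,
                           lever_arm_mm=1.0)
        with pytest.raises(ValueError):
            dipole_field_angle(g, 0.0)

    def test_45_tilt_changes_estimated_sensitivity_below_5pct(self):
        theta = np.arange(-90.0, 90.0, 0.1)
        out = {}
        for tilt in (0.0, 45.0):
            g = MagnetGeometry(vertical_distance_mm=3.0, tilt_deg=tilt)
            phi = dipole_field_angle(g, theta)
            amp = sensitivity_profile(g)
            v = amr_response(phi, AMRSensorSpec(peak_amplitude_mV=amp,
                                                noise_sd_mV=0.0))
            out[tilt] = estimate_sensitivity(theta, v)
        rel = np.abs(out[45.0] / out[0.0] - 1.0)
        assert np.all(rel < 0.05)


class TestEstimateSensitivity:
    def test_pure_sin2theta_matches_closed_form(self):
        theta = np.arange(-90.0, 90.0001, 0.1)
        v = 1000.0 * np.sin(np.deg2rad(2 * theta))
        est = estimate_sensitivity(theta, v)[0]
        assert est == pytest.approx(1000.0 * MEAN_SLOPE_PER_AMPLITUDE, rel=5e-3)

    def test_constant_channel_not_estimable(self):
        theta = np.linspace(-30, 30, 100)
        est = estimate_sensitivity(theta, np.full_like(theta, 7.0))
        assert np.isnan(est[0])

    def test_linear_sweep_returns_its_slope(self):
        theta = np.linspace(-30, 30, 601)
        est = estimate_sensitivity(theta, 50.0 * theta)
        assert est[0] == pytest.approx(50.0, rel=1e-6)

    def test_two_channel_sweep_estimates_both(self):
        theta = np.arange(-90.0, 90.0001, 0.1)
        v = amr_response(theta, spec_a1000())
        est = estimate_sensitivity(theta, v)
        assert est == pytest.approx([1000.0 * MEAN_SLOPE_PER_AMPLITUDE] * 2,
                                    rel=5e-3)

    def test_windowed_slope_option_on_noisy_sweep(self):
        rng = np.random.default_rng(0)
        theta = np.arange(-90.0, 90.0001, 0.1)
        v = 1000.0 * np.sin(np.deg2rad(2 * theta)) + rng.normal(0, 5, theta.size)
        est = estimate_sensitivity(theta, v, slope_window_deg=1.0)
        assert est[0] == pytest.approx(1000.0 * MEAN_SLOPE_PER_AMPLITUDE, rel=0.02)

    def test_nonmonotone_sweep_rejected(self):
        with pytest.raises(ValueError):
            estimate_sensitivity(np.array([0.0, 1.0, 0.5]), np.zeros(3))


class TestSimulateSensorTrace:
    def _eye(self, pos, fs=1000.0):
        t = np.arange(pos.size) / fs
        return EyeTrace(t, pos, fs)

    def test_constant_eye_noise_free_is_constant(self):
        eye = self._eye(np.full(500, 4.0))
        tr = simulate_sensor_trace(eye, AMRSensorSpec(noise_sd_mV=0.0),
                                   MagnetGeometry(vertical_distance_mm=0.0))
        assert np.ptp(tr.v_mV, axis=0) == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_small_angle_channel1_linear_in_eye_angle(self):
        t = np.arange(0, 5, 1e-3)
        eye = EyeTrace(t, 10.0 * np.sin(2 * np.pi * t), 1000.0)
        spec = AMRSensorSpec(noise_sd_mV=0.0)
        geom = MagnetGeometry(vertical_distance_mm=0.0)
        tr = simulate_sensor_trace(eye, spec, geom)
        pred = spec.peak_amplitude_mV * np.pi / 90.0 * eye.position_deg
        r = np.corrcoef(pred, tr.v_mV[:, 0])[0, 1]
        assert r**2 > 0.999

    def test_seeded_runs_bit_identical(self):
        eye = self._eye(np.linspace(-5, 5, 1000))
        a = simulate_sensor_trace(eye, seed=42)
        b = simulate_sensor_trace(eye, seed=42)
        assert np.array_equal(a.v_mV, b.v_mV)
        c = simulate_sensor_trace(eye, seed=43)
        assert not np.array_equal(a.v_mV, c.v_mV)

    def test_ttl_train_spacing(self):
        eye = self._eye(np.zeros(10_000))
        tr = simulate_sensor_trace(eye, ttl_rate_hz=1.0)
        assert np.allclose(np.diff(tr.ttl_pulse_times_s), 1.0)

    def test_empty_trace_rejected(self):
        eye = EyeTrace(np.array([]), np.array([]), 1000.0)
        with pytest.raises(ValueError):
            simulate_sensor_trace(eye)

    def test_k_true_is_reciprocal_small_angle_sensitivity(self):
        spec = AMRSensorSpec(noise_sd_mV=0.0)
        geom = MagnetGeometry(vertical_distance_mm=0.0)
        s = small_angle_sensitivity(spec, geom)
        assert s == pytest.approx(spec.peak_amplitude_mV * np.pi / 90.0)
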