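"""Ground-truth generators: stimulus, eye kinematics, projections, renders."""

import numpy as np
import pytest

from magtrack.sensor_model import AMRSensorSpec, small_angle_sensitivity
from magtrack.synthetic_data import (
    EyeImageSpec,
    EyeKinematicsSpec,
    generate_eye_trace,
    generate_overhead_motion,
    generate_session,
    generate_stimulus,
    project_to_cameras,
    render_eye_frames,
)
from magtrack.video_geometry import CameraRig, forward_deltas


class TestGenerateStimulus:
    def test_position_amplitude_is_integral_of_velocity(self):
        st = generate_stimulus(1.0, 10.0, 10.0, 1000.0)
        assert np.max(np.abs(st.position_deg)) == pytest.approx(10.0 / (2 * np.pi),
                                                                rel=1e-3)

    def test_velocity_starts_at_zero_rising(self):
        st = generate_stimulus(0.5, 10.0, 10.0, 1000.0)
        assert st.velocity_deg_s[0] == pytest.approx(0.0, abs=1e-9)
        assert st.velocity_deg_s[1] > 0

    def test_sample_count(self):
        st = generate_stimulus(1.0, 10.0, 10.0, 1000.0)
        assert len(st.time_s) == 10_000

    def test_velocity_is_derivative_of_position(self):
        st = generate_stimulus(2.0, 10.0, 5.0, 1000.0)
        num = np.gradient(st.position_deg, st.time_s)
        assert np.allclose(num[10:-10], st.velocity_deg_s[10:-10], atol=0.05)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            generate_stimulus(0.0, 10.0, 10.0, 1000.0)


class TestGenerateEyeTrace:
    def test_pure_slow_phase_antiphase_to_stimulus(self):
        st = generate_stimulus(1.0, 10.0, 10.0, 1000.0)
        kin = EyeKinematicsSpec(response_gain=0.5, saccade_rate_hz=0.0,
                                fixation_jitter_sd_deg=0.0)
        eye = generate_eye_trace(st, kin, seed=0)
        vel = np.gradient(eye.position_deg, eye.time_s)
        # amplitude 5 deg/s, antiphase
        assert np.max(np.abs(vel[50:-50])) == pytest.approx(5.0, rel=0.01)
        assert np.corrcoef(vel, st.velocity_deg_s)[0, 1] == pytest.approx(-1.0,
                                                                          abs=1e-3)

    def test_zero_gain_leaves_saccades_and_jitter_only(self):
        st = generate_stimulus(1.0, 10.0, 10.0, 1000.0)
        kin = EyeKinematicsSpec(response_gain=0.0, saccade_rate_hz=0.0,
                                fixation_jitter_sd_deg=0.0)
        eye = generate_eye_trace(st, kin, seed=0)
        assert np.ptp(eye.position_deg) == pytest.approx(0.0, abs=1e-12)

    def test_poisson_saccade_count_within_3sd(self):
        st = generate_stimulus(1.0, 10.0, 300.0, 200.0)
        kin = EyeKinematicsSpec(response_gain=0.0, saccade_rate_hz=0.2,
                                fixation_jitter_sd_deg=0.0,
                                sample_rate_hz=200.0)
        eye = generate_eye_trace(st, kin, seed=5)
        vel = np.abs(np.gradient(eye.position_deg, eye.time_s))
        # 20 ms ramps: count distinct supra-threshold runs
        over = vel > 50.0
        n_sacc = int(np.sum(over[1:] & ~over[:-1]) + over[0])
        mean = 0.2 * 300.0
        assert abs(n_sacc - mean) <= 3 * np.sqrt(mean)

    def test_seeded_determinism(self):
        st = generate_stimulus(1.0, 10.0, 20.0, 500.0)
        kin = EyeKinematicsSpec(sample_rate_hz=500.0)
        a = generate_eye_trace(st, kin, seed=9)
        b = generate_eye_trace(st, kin, seed=9)
        assert np.array_equal(a.position_deg, b.position_deg)


class TestProjectToCameras:
    def _const_eye(self, angle, dur=1.0, fs=1000.0):
        from magtrack.core import EyeTrace

        t = np.arange(0, dur, 1 / fs)
        return EyeTrace(t, np.full(t.size, float(angle)), fs)

    def test_zero_angle_symmetric_deltas(self, rig):
        frames = project_to_cameras(self._const_eye(0.0), rig, r_p_mm=1.0,
                                    pixel_noise_sd=0.0)
        expected = np.sin(np.deg2rad(20.0))
        assert np.allclose(frames.delta_mm, expected, atol=1e-9)

    def test_pupil_on_camera1_axis(self, rig):
        frames = project_to_cameras(self._const_eye(20.0), rig, r_p_mm=1.0,
                                    pixel_noise_sd=0.0)
        assert np.allclose(frames.delta_mm[:, 1], np.sin(np.deg2rad(40.0)), atol=1e-9)
        assert np.allclose(frames.delta_mm[:, 0], 0.0, atol=1e-9)

    def test_10deg_with_rp_1p5(self, rig):
        frames = project_to_cameras(self._const_eye(10.0), rig, r_p_mm=1.5,
                                    pixel_noise_sd=0.0)
        assert frames.delta_mm[0, 0] == pytest.approx(1.5 * np.sin(np.deg2rad(10.0)),
                                                      abs=1e-9)
        assert frames.delta_mm[0, 1] == pytest.approx(0.75, abs=1e-9)

    def test_frame_rate_is_30hz(self, rig):
        frames = project_to_cameras(self._const_eye(0.0, dur=2.0), rig)
        assert np.allclose(np.diff(frames.time_s), 1 / 30.0)

    def test_out_of_range_angle_flagged_not_clipped(self, rig):
        frames = project_to_cameras(self._const_eye(85.0), rig, pixel_noise_sd=0.0)
        assert not frames.valid.any()


class TestRenderEyeFrames:
    def _series(self, pupil_xy, cr_xy=(320.0, 240.0)):
        from magtrack.video_geometry import PupilFrameSeries

        pupil = np.tile(np.asarray(pupil_xy, float), (1, 2, 1))
        cr = np.tile(np.asarray(cr_xy, float), (1, 2, 1))
        return PupilFrameSeries(np.array([0.0]), pupil, cr, 0.005)

    def test_darkest_neighborhood_at_pupil_center(self):
        spec = EyeImageSpec(noise_sd=0.0)
        img = render_eye_frames(self._series((250.0, 200.0)), spec, seed=0)[0, 0]
        # the pupil interior is a dark plateau: locate its centroid
        dark = img <= img.min() + 5
        ys, xs = np.nonzero(dark)
        assert abs(xs.mean() - 250.0) <= 1 and abs(ys.mean() - 200.0) <= 1

    def test_brightest_pixel_at_reference_cr(self):
        spec = EyeImageSpec(noise_sd=0.0)
        img = render_eye_frames(self._series((200.0, 240.0)), spec, seed=0)[0, 0]
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        # distractor sits at 40 px offset; reference is at the image center
        assert (ix, iy) in {(320, 240), (280, 240)}
        assert img[240, 320] == img.max()

    def test_seeded_renders_identical(self):
        s = self._series((320.0, 240.0))
        a = render_eye_frames(s, seed=3)
        b = render_eye_frames(s, seed=3)
        assert np.array_equal(a, b)

    def test_pupil_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            render_eye_frames(self._series((630.0, 240.0)),
                              EyeImageSpec(noise_sd=0.0), seed=0)


class TestOverheadMotion:
    def test_static_scene_motion_at_noise_floor(self):
        frames, labels, fr = generate_overhead_motion([(2.0, 0.0)], seed=0,
                                                      noise_sd=0.5)
        diffs = np.abs(np.diff(frames.astype(float), axis=0)).mean(axis=(1, 2))
        assert diffs.mean() < 1.0

    def test_activity_levels_strictly_ordered(self):
        frames, labels, fr = generate_overhead_motion(
            [(4.0, 0.0), (4.0, 1.0), (4.0, 3.0)], seed=1)
        diffs = np.abs(np.diff(frames.astype(float), axis=0)).mean(axis=(1, 2))
        means = [diffs[labels[1:] == lvl].mean() for lvl in (0, 1, 2)]
        assert means[0] < means[1] < means[2]

    def test_seeded_determinism(self):
        a = generate_overhead_motion([(1.0, 1.0)], seed=4)[0]
        b = generate_overhead_motion([(1.0, 1.0)], seed=4)[0]
        assert np.array_equal(a, b)


class TestGenerateSession:
    def test_default_session_counts(self, session_bundle):
        b = session_bundle
        assert len(b.sensor) == 60_000
        assert b.sensor.ttl_pulse_times_s.size == 60
        assert b.flash_frame_indices.size >= 58  # latency trims edge flashes

    def test_k_true_matches_sensor_amplitude(self, session_bundle):
        b = session_bundle
        expected = 1.0 / small_angle_sensitivity(b.sensor_spec, b.geometry)
        assert b.k_true_deg_per_mV == pytest.approx(expected)

    def test_clean_session_video_matches_truth(self, clean_bundle):
        from magtrack.video_geometry import eye_position_from_frames

        b = clean_bundle
        rec = eye_position_from_frames(b.camera, b.rig)
        t_sensor = b.camera_latency_s + (1 + b.clock_drift) * b.camera.time_s
        true = np.interp(t_sensor, b.eye.time_s, b.eye.position_deg)
        assert np.nanmax(np.abs(rec.position_deg - true)) < 1e-6

    def test_session_reproducible_under_seed(self):
        a = generate_session(seed=2, duration_s=5.0)
        b = generate_session(seed=2, duration_s=5.0)
        assert np.array_equal(a.sensor.v_mV, b.sensor.v_mV)
        assert np.array_equal(a.camera.pupil_px, b.camera.pupil_px)
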