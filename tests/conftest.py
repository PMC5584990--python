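import numpy as np
import pytest
from hypothesis import settings

from magtrack.sensor_model import AMRSensorSpec

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from magtrack.synthetic_data import EyeKinematicsSpec, generate_session
from magtrack.video_geometry import CameraRig


@pytest.fixture(scope="session")
def rig():
    return CameraRig()


@pytest.fixture(scope="session")
def session_bundle():
    """Default-condition calibration session (60 s, 1 Hz, +/-10 deg/s)."""
    return generate_session(seed=11)


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise- and saccade-free session for exactness checks."""
    kin = EyeKinematicsSpec(saccade_rate_hz=0.0, fixation_jitter_sd_deg=0.0)
    return generate_session(
        seed=12, kinematics=kin,
        sensor_spec=AMRSensorSpec(noise_sd_mV=0.0), pixel_noise_sd=0.0)
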