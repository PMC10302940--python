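import numpy as np
import pytest

from armimu.config import RunConfig
from armimu.synthgen import (
    ArmGeometry,
    imu_from_trajectory,
    simulate_arm,
    stance_swing_profile,
)


@pytest.fixture(scope="session")
def geometry():
    return ArmGeometry(l1=30.0, l2=25.0)


@pytest.fixture(scope="session")
def gait_trajectory(geometry):
    """Stance/swing arm motion, no contraction: crisp ground-truth stationarity."""
    profiles = (
        stance_swing_profile(0.35, 1.1, 2.5, 0.4),
        stance_swing_profile(0.3, 1.0, 2.5, 0.4),
    )
    return simulate_arm(geometry, profiles, duration=10.0, dt=0.01, contraction_amplitude=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_trace(gait_trajectory):
    """Noiseless, bias-free IMU observation of the gait trajectory."""
    return imu_from_trajectory(gait_trajectory, seed=0)


@pytest.fixture(scope="session")
def noisy_trace(gait_trajectory):
    cfg = RunConfig()
    s = cfg.synth
    return imu_from_trajectory(
        gait_trajectory,
        bias_a=s.bias_a,
        bias_g=s.bias_g,
        noise_std_a=s.noise_std_a,
        noise_std_g=s.noise_std_g,
        seed=11,
    )
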