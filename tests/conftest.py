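import numpy as np
import pytest

from stridespeed import (
    ImuRecording,
    SimulationConfig,
    StrideWindow,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """200 synthetic canter strides through the full segmentation pipeline."""
    return simulate_dataset(200, seed=42)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimulationConfig(accel_noise_sd_g=0.0, gyro_noise_sd_dps=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(n=500, sample_rate=100.0, az=None, seed=0):
    """A small in-range recording; az can be injected for peak tests."""
    r = np.random.default_rng(seed)
    accel = 0.01 * r.standard_normal((n, 3))
    accel[:, 2] += 1.0
    if az is not None:
        accel[:, 2] = az
    gyro = 1.0 * r.standard_normal((n, 3))
    return ImuRecording(sample_rate_hz=sample_rate, accel=accel, gyro=gyro)


def random_window(rng, gravity=1.0, scale=0.3):
    """A random smooth-ish stride window with observable gravity on Z."""
    data = scale * rng.standard_normal((6, 101))
    data[2] += gravity
    return StrideWindow(data=data, anchor_index=0)
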