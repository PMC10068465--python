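import warnings

import numpy as np
import pytest

from rippleloc import Recording, make_toy_forward_model


@pytest.fixture(scope="session")
def forward_model():
    """Shared toy forward model: 64 sensors, 96 grid points, 90 ROIs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_toy_forward_model(64, 96, "spherical-toy", seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=1000.0):
    return Recording(data=np.asarray(data, dtype=float), fs=fs)


@pytest.fixture
def sine_recording():
    """Five channels of a clean 150 Hz tone, 2 s at 1 kHz."""
    t = np.arange(2000) / 1000.0
    data = np.tile(np.sin(2 * np.pi * 150 * t), (5, 1))
    return make_recording(data)
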