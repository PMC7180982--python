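"""Shared fixtures: small synthetic recordings built at test time."""

import numpy as np
import pytest

import hfsleep as hf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pairs():
    """Three synthetic subjects x 40 epochs at 500 Hz (default leakage).

    The seed is chosen so the pooled hypnograms cover all five stages,
    which the correlation-table fixtures require.
    """
    return hf.simulate_dataset(3, n_epochs=40, seed=2)


@pytest.fixture(scope="session")
def small_recording(small_pairs):
    return small_pairs[0][0]


@pytest.fixture(scope="session")
def small_hypnogram(small_pairs):
    return small_pairs[0][1]


@pytest.fixture(scope="session")
def ramp_recording():
    """Deterministic ramp signal, 5 epochs at 200 Hz: slicing oracle."""
    fs = 200.0
    n = int(fs * 30) * 5
    x = np.arange(n, dtype=float)
    return hf.Recording(subject_id="ramp", fs=fs, channels={"C3-A2": x})
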