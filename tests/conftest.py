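import numpy as np
import pytest

from tfchannel import KineticParams, SimConfig

# the three worked-example promoters used throughout the tests:
# (a) fast, high-threshold; (b) slow activation; (c) fast, low-threshold
FIG_A = KineticParams(k1=1.0, k2=100.0, n=10.0, Kd=70.0, d1=0.01)
FIG_B = KineticParams(k1=0.01, k2=1.0, n=1.0, Kd=10.0, d1=1.0)
FIG_C = KineticParams(k1=1.0, k2=100.0, n=1.0, Kd=10.0, d1=0.01)


@pytest.fixture(scope="session")
def fig_a():
    return FIG_A


@pytest.fixture(scope="session")
def fig_b():
    return FIG_B


@pytest.fixture(scope="session")
def fig_c():
    return FIG_C


@pytest.fixture
def fast_config():
    """Small, quick simulation configuration for unit tests."""
    return SimConfig(dt=0.05, total_time=100.0, n_reps=20, seed=99)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
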