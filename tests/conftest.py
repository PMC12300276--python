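import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emgseq import SimConfig, analyze_session, simulate_session

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_session():
    """One reproducible 8-punch session with the default (measured) onsets."""
    cfg = SimConfig(n_punches=8, seed=1)
    emg, accel, truth = simulate_session(cfg)
    return cfg, emg, accel, truth


@pytest.fixture(scope="session")
def analyzed(small_session):
    cfg, emg, accel, truth = small_session
    return analyze_session(emg, accel), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
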