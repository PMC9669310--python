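import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pkjpause import (
    PauseModel,
    Protocol,
    SpontaneousModel,
    Trial,
    generate_cell_recording,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def protocol():
    return Protocol(cs_us_interval=0.3, cs_duration=0.3, iti=15.0)


@pytest.fixture
def regular_trial():
    """Clock-like 100-Hz trial over [-1, 1.1] s with a silent gap in [0.1, 0.3]."""
    t = np.arange(-1.0, 1.1, 0.01)
    t = t[(t < 0.1) | (t > 0.3)]
    return Trial(spike_times=t, record_start=-1.0, record_end=1.1)


@pytest.fixture(scope="session")
def probe_recording():
    """One default-generator probe cell (20 trials, T = 0.3 s) plus truth."""
    proto = Protocol(cs_us_interval=0.3, cs_duration=0.3, iti=15.0)
    return generate_cell_recording(proto, n_trials=20, seed=77)
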