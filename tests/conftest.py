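import numpy as np
import pytest

from linebp import SimulationConfig, noiseless, simulate_session


@pytest.fixture(scope="session")
def short_session():
    """A 120 s noisy session with frequent cuffs (pump on from t=0)."""
    cfg = SimulationConfig(duration_s=120.0, cuff_interval_s=30.0, seed=1)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def noiseless_session():
    """A 300 s disturbance-free session with constant true C = 6."""
    cfg = noiseless(SimulationConfig(duration_s=300.0, cuff_interval_s=60.0, seed=2))
    return simulate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
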