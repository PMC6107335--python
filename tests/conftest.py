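import numpy as np
import pytest

from crchain import EyelidTrace, GenParams, PCGenParams, ProtocolConfig, generate_session
from crchain.pipeline import decompose_session

GRID = np.arange(-200.0, 2300.0)


def make_trace(samples, t0=-200.0, eye="left"):
    return EyelidTrace(samples=np.asarray(samples, dtype=float), t0=t0, eye=eye)


def flat_trace():
    return make_trace(np.zeros(2500))


def ramp_trace(t_start=300.0, t_stop=500.0, peak=1.0):
    """Linear rise from 0 at t_start to peak at t_stop, then held."""
    t = GRID
    y = np.clip((t - t_start) / (t_stop - t_start), 0.0, 1.0) * peak
    return make_trace(y)


@pytest.fixture(scope="session")
def chained_session():
    """Default ipsilateral training session, chained generator."""
    return generate_session(ProtocolConfig(), GenParams(), seed=101)


@pytest.fixture(scope="session")
def chained_outcomes(chained_session):
    return decompose_session(chained_session)


@pytest.fixture(scope="session")
def spike_session():
    """Small ipsilateral session with one simulated eyelid PC."""
    cfg = ProtocolConfig(n_blocks=6)
    return generate_session(cfg, GenParams(), PCGenParams(), seed=202)
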