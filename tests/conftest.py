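import numpy as np
import pytest

from septorhythm import AnalysisConfig, Lfp, SessionSpec, generate_session


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_session():
    """One 300 s study-like synthetic session, shared across test modules."""
    return generate_session(SessionSpec(duration=300.0, rng_seed=1))


def sine_lfp(freq, duration=10.0, rate=1000.0, amp=1.0, phase0=0.0, offset=0.0):
    """Pure sinusoid with a trough at t=0 when phase0=0 (x = -cos)."""
    t = np.arange(int(duration * rate)) / rate
    return Lfp(offset - amp * np.cos(2 * np.pi * freq * t + phase0), rate=rate)


@pytest.fixture
def theta_sine():
    return sine_lfp(8.0)
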