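import numpy as np
import pytest

from steercouple import SessionSpec, gen_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One seeded session with enough trials for event-level checks."""
    return gen_session(SessionSpec(n_trials_left=8, n_trials_right=8, seed=42))


@pytest.fixture(scope="session")
def tiny_spec():
    return SessionSpec(n_trials_left=2, n_trials_right=2, seed=7)
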