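import numpy as np
import pytest

from bayesage import DEFAULT_TRANSITION, REFERENCE_PRIORS


@pytest.fixture(scope="session")
def reference_priors():
    """The four bundled American male Gompertz priors."""
    return REFERENCE_PRIORS


@pytest.fixture(scope="session")
def donated_prior():
    return REFERENCE_PRIORS["donated"]


@pytest.fixture(scope="session")
def default_transition():
    """Documented synthetic 8-phase transition model (tau = ln{30..85}, sigma 0.25)."""
    return DEFAULT_TRANSITION


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
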