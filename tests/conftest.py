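import numpy as np
import pytest

from netflock.fixtures import make_fixtures


@pytest.fixture(scope="session")
def toys():
    """Deterministic toy instances shared across suites."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def lattice9(toys):
    return toys["lattice_9"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
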