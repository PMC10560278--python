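import numpy as np
import pytest

from bcinav import Grid, identity_profile


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_grid():
    return Grid(9, 1)


@pytest.fixture(scope="session")
def large_grid():
    return Grid(20, 20)


@pytest.fixture(scope="session")
def perfect_profile():
    return identity_profile()
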