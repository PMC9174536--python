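import numpy as np
import pytest

from angioseg import make_fixture


@pytest.fixture(scope="session")
def fixture_pairs():
    """The standard 4-image 96x96 seeded phantom fixture."""
    return make_fixture(n=4, size=96, seed=1)


@pytest.fixture(scope="session")
def small_pairs():
    """A faster 64x64 fixture for short training smoke tests."""
    return make_fixture(n=2, size=64, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
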