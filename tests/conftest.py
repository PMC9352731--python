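import numpy as np
import pytest

from spinedrift.chain import ChainSpec
from spinedrift.fixtures import default_spec, fixture_grid


@pytest.fixture(scope="session")
def spec3():
    """Three-state worked example used throughout the unit tests."""
    return ChainSpec(x=(0.5, 0.3, 0.2), y=(0.2, 0.1))


@pytest.fixture(scope="session")
def spec2():
    """Symmetric two-state chain with closed-form passage quantities."""
    return ChainSpec(x=(0.5, 0.5), y=(0.2,))


@pytest.fixture(scope="session")
def canonical():
    return default_spec()


@pytest.fixture(scope="session")
def grid():
    """Deterministic corpus of 12 valid chains across families and sizes."""
    return fixture_grid(12, seed=2024)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
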