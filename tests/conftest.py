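import numpy as np
import pytest

from ratdrive import ParameterSet


@pytest.fixture
def defaults() -> ParameterSet:
    """Default parameterization (2 km island, 1000 / km^2, no drive)."""
    return ParameterSet()


@pytest.fixture
def small_params() -> ParameterSet:
    """Small, fast configuration: 1 km island, 600 individuals."""
    return ParameterSet(density=600.0, island_side=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
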