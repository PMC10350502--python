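import numpy as np
import pytest

from microspike import LaserParams, load_default_font


@pytest.fixture(scope="session")
def params() -> LaserParams:
    """Default semiconductor-micropillar parameter set."""
    return LaserParams()


@pytest.fixture(scope="session")
def font():
    return load_default_font()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230703)
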