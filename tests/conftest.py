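import numpy as np
import pytest

from habstruct import HeightMap, SimParams, midpoint_displacement


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_fbm():
    """129x129 midpoint-displacement surface, H=0.5."""
    return midpoint_displacement(SimParams(hurst=0.5, level=7, seed=7))


@pytest.fixture
def ramp_map():
    """Deterministic non-flat 9x9 heightmap."""
    z = np.add.outer(np.arange(9.0), np.arange(9.0) ** 1.5)
    return HeightMap(z, cell_size=0.5)
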