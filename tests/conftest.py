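import numpy as np
import pytest

from mistlemap import HabitatRegion


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def unit_square():
    return HabitatRegion.from_vertices([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def km_square():
    return HabitatRegion.from_rectangle(1000.0, 1000.0)
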