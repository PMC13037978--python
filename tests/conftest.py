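import numpy as np
import pytest

from vcgsim import TankConfig, make_triangle


@pytest.fixture
def triangle():
    return make_triangle(100.0)


@pytest.fixture
def tank_cfg(triangle):
    return TankConfig(triangle=triangle)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
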