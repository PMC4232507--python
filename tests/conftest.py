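import numpy as np
import pytest

from adafa import AdaptiveConfig, FAConfig, SearchSpace
from adafa.benchmarks import get_problem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_space():
    return SearchSpace(3, -5.0, 5.0)


@pytest.fixture
def tiny_fa_cfg():
    return FAConfig(pop_size=10, max_gen=50, seed=7)


@pytest.fixture
def ada_cfg():
    return AdaptiveConfig()


@pytest.fixture
def sphere2d():
    return get_problem("f1", 2)
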