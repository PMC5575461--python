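import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from andesdiv.trees import parse_newick

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_tip_tree():
    return parse_newick("(A:10,B:10);")


@pytest.fixture
def balanced_four():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
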