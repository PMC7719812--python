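import numpy as np
import pytest
from hypothesis import settings

from closurenet.design import Picture, build_erp_block

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def pictures():
    """Ten distinct 40-segment pictures."""
    return [Picture(f"pic{i:02d}", tuple(range(40))) for i in range(10)]


@pytest.fixture
def erp_block(pictures):
    return build_erp_block(pictures, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
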