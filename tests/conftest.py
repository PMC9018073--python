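import numpy as np
import pytest

from spindlesim import wild_type_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wt_params():
    return wild_type_params()


class FixedUniform:
    """Random-source stub emitting a prescribed uniform sequence."""

    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


@pytest.fixture
def fixed_uniform():
    return FixedUniform
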