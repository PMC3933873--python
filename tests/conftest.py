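import numpy as np
import pytest

from pestitch import BaseFrequencies


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform() -> BaseFrequencies:
    return BaseFrequencies.uniform()
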