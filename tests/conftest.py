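import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
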