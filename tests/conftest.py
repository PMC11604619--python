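import numpy as np
import pytest

from countner import BC5CDR_SCHEME, CONLL_SCHEME


@pytest.fixture
def conll_scheme():
    return CONLL_SCHEME


@pytest.fixture
def bc5_scheme():
    return BC5CDR_SCHEME


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
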