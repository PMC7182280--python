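import numpy as np
import pytest

from dotgsa import random_pd_correlation


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_corr_10():
    return random_pd_correlation(10, seed=7)
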