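import numpy as np
import pytest

from lmskit.simdata import synthetic_signature_set


@pytest.fixture(scope="session")
def sigset3():
    """Three synthetic signatures with zero cutoffs."""
    return synthetic_signature_set(3, seed=0)


@pytest.fixture(scope="session")
def sigset5():
    return synthetic_signature_set(5, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
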