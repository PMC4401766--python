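import numpy as np
import pytest

from gliokin import LN229, U87


@pytest.fixture(scope="session")
def ln229():
    return LN229


@pytest.fixture(scope="session")
def u87():
    return U87


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
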