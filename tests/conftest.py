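import warnings

import numpy as np
import pytest

from syrinx.songmodel import default_model


@pytest.fixture(autouse=True)
def _quiet_overflow():
    # the trust-region guard handles the rare expm overflow internally
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def model():
    return default_model(1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
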