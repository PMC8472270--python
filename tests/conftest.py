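import numpy as np
import pytest

import pepassoc as pa


@pytest.fixture
def config():
    return pa.InstrumentConfig()


@pytest.fixture
def exendin():
    return pa.PeptideRecord("exendin-4", pa.EXENDIN4_SEQUENCE)


@pytest.fixture
def trimer_model():
    return pa.default_exendin_model()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
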