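import numpy as np
import pytest

from tumorlens.phantom import PhantomSpec


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
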