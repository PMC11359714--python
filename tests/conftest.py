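import numpy as np
import pytest

from eegdense.montage import builtin_split, load_builtin_montage


@pytest.fixture(scope="session")
def montage():
    return load_builtin_montage()


@pytest.fixture(scope="session")
def split18(montage):
    return builtin_split(18, montage)


@pytest.fixture
def rng():
    return np.random.default_rng(20240812)
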