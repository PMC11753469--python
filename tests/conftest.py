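import numpy as np
import pytest
from hypothesis import settings

from phagetarget.catalogue import DEFAULT_GENES, default_survival_entries

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genes():
    return list(DEFAULT_GENES)


@pytest.fixture(scope="session")
def survival():
    return list(default_survival_entries())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
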