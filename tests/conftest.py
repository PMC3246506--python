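import numpy as np
import pytest
from hypothesis import settings

import heteropatry as hp

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def env():
    return hp.Environment()


@pytest.fixture
def specialist1():
    return hp.fixture_genomes("specialist1", 1)[0]


@pytest.fixture
def specialist3():
    return hp.fixture_genomes("specialist3", 1)[0]


@pytest.fixture
def generalist():
    return hp.fixture_genomes("generalist", 1)[0]
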