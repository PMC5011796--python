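import numpy as np
import pytest

from rgnact import LifeTable, fixture_parameter_set, synthetic_life_table
from rgnact.markov import ModelInputs


@pytest.fixture(scope="session")
def pset():
    return fixture_parameter_set()


@pytest.fixture(scope="session")
def life_table():
    return synthetic_life_table()


@pytest.fixture(scope="session")
def zero_life_table():
    return LifeTable.zero()


@pytest.fixture(scope="session")
def base_inputs(pset):
    return ModelInputs.from_means(pset)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160905)
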