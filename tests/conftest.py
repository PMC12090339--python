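import numpy as np
import pytest

from fretlearn import (REGION_A, REGION_B, KineticParams, enumerate_space,
                       make_landscape, random_library)
from fretlearn.sequence_space import VariantOneHotEncoder


@pytest.fixture(scope="session")
def region_b():
    return REGION_B


@pytest.fixture(scope="session")
def region_a():
    return REGION_A


@pytest.fixture(scope="session")
def space_b():
    return enumerate_space(REGION_B)


@pytest.fixture(scope="session")
def encoder_b():
    return VariantOneHotEncoder(REGION_B).fit()


@pytest.fixture(scope="session")
def dense_landscape():
    return make_landscape(REGION_B, "dense", seed=3)


@pytest.fixture(scope="session")
def library48():
    return random_library(REGION_B, 48, seed=1)


@pytest.fixture(scope="session")
def noiseless_kinetics():
    return KineticParams(noise_sd=0.0)
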