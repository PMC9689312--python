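import numpy as np
import pytest

from brewkin import default_designs, make_dataset
from brewkin.params import default_params


@pytest.fixture(scope="session")
def biomass_truth():
    return default_params("biomass")


@pytest.fixture(scope="session")
def co2_truth():
    return default_params("co2")


@pytest.fixture(scope="session")
def designs():
    return default_designs()


@pytest.fixture(scope="session")
def training_designs(designs):
    """Batches 2-4: the multi-temperature partition used for identification."""
    return designs[1:]


@pytest.fixture(scope="session")
def biomass_clean(biomass_truth, training_designs):
    """Noise-free biomass-model measurement sets for designs 2-4."""
    return [make_dataset("biomass", biomass_truth, d, sigma_rel=0.0)
            for d in training_designs]


@pytest.fixture(scope="session")
def co2_clean(co2_truth, training_designs):
    """Noise-free CO2-model measurement sets for designs 2-4."""
    return [make_dataset("co2", co2_truth, d, sigma_rel=0.0)
            for d in training_designs]
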