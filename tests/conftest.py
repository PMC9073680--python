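import numpy as np
import pytest
from hypothesis import settings

from hornscan import polarize as pol
from hornscan.simulate import default_config, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: seed of the shared study-design dataset used across the suite
DATASET_SEED = 1


@pytest.fixture(scope="session")
def dataset():
    """The default study-design simulation (three populations, two
    inversions, pseudogene), shared across tests."""
    return simulate_dataset(default_config(DATASET_SEED))


@pytest.fixture(scope="session")
def decisions(dataset):
    """Polarization decisions for every site of the shared dataset."""
    return pol.polarize_table(dataset.table, dataset.outgroup)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
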