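import numpy as np
import pytest

from mdsweave._codes import get_tables
from mdsweave.io import bundle_from_simulation
from mdsweave.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully featured simulated dataset (species evolution on)."""
    cfg = SimulationConfig(seed=42, n_loci=12, n_background_genes=20,
                           n_decoy_noncoding=2, n_decoy_identical=2,
                           n_decoy_low_penetration=2, correction_prob=0.3)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_dataset):
    return bundle_from_simulation(small_dataset)


@pytest.fixture(scope="session")
def tables6():
    return get_tables(6)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
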