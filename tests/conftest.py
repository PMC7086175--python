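import numpy as np
import pytest

from orgflux.simulate import SimConfig, simulate_dataset, simulate_species_tree
from orgflux.trees import read_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_species_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def reference_dataset():
    """One medium dataset with planted post-duplication effect, shared by
    the slower integration tests."""
    return simulate_dataset(
        SimConfig(n_species=12, n_orthogroups=15, kappa=5.0), seed=42
    )
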