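import numpy as np
import pytest

from tuberkit.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=1, n_contigs=2, contig_length=100_000,
                            n_genes=20, n_tes=30)


@pytest.fixture(scope="session")
def small_genome(small_config):
    """A 2 x 100 kb genome with 20 genes and 30 TEs."""
    return simulate_genome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
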