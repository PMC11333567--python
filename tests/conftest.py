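import numpy as np
import pytest

from squigmap.indexing import build_index
from squigmap.pore_model import make_synthetic_model
from squigmap.simulator import SimParams, random_genome, simulate_reads


@pytest.fixture(scope="session")
def model6():
    """Synthetic 6-mer pore model shared across tests."""
    return make_synthetic_model(k=6, seed=0)


@pytest.fixture(scope="session")
def model1():
    return make_synthetic_model(k=1, seed=0)


@pytest.fixture(scope="session")
def genome_100k():
    return random_genome(100_000, seed=7)


@pytest.fixture(scope="session")
def index_100k(genome_100k, model6):
    return build_index([genome_100k], model6)


@pytest.fixture(scope="session")
def e2e_scenario(genome_100k, model6, index_100k):
    """The default end-to-end scenario: 100 kb random genome, 200 reads at
    450 b/s / 4 kHz with moderate noise, mapped with default parameters.

    Session-scoped because several tests measure different properties of
    the same mapping run.
    """
    from squigmap.mapping import map_read

    reads, truth = simulate_reads(
        [genome_100k], model6, SimParams(n_reads=200, rng_seed=3))
    records = [map_read(r, index_100k) for r in reads]
    return {"reads": reads, "truth": truth, "records": records}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
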