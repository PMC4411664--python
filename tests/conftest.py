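import pytest

from splicemap import read_simulator as sim
from splicemap.params import MappingParams
from splicemap.pipeline import map_reads


@pytest.fixture(scope="session")
def small_world():
    """A compact simulated locus set shared by pipeline-level tests."""
    genome = sim.simulate_genome(80_000, 0.5, seed=51)
    models, genome = sim.simulate_genes(genome, 6, seed=52)
    return genome, models


@pytest.fixture(scope="session")
def clean_mapping(small_world):
    genome, models = small_world
    reads, truths = sim.simulate_reads(
        models,
        genome,
        n_reads=1200,
        multi_junction_weights={0: 0.6, 1: 0.35, 2: 0.05},
        seed=53,
    )
    result = map_reads([genome], reads)
    return genome, reads, truths, result


@pytest.fixture(scope="session")
def noisy_mapping(small_world):
    genome, models = small_world
    reads, truths = sim.simulate_reads(
        models,
        genome,
        n_reads=1500,
        mismatch_rate=0.01,
        indel_rate=0.002,
        multi_junction_weights={0: 0.6, 1: 0.35, 2: 0.05},
        seed=54,
    )
    result = map_reads([genome], reads)
    return genome, reads, truths, result


@pytest.fixture
def params():
    return MappingParams()
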