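import numpy as np
import pytest

from cceqtl.genome import GenomeSpec
from cceqtl.simulate import dosage_from_mosaic, simulate_cc_population


@pytest.fixture(scope="session")
def small_genome():
    return GenomeSpec([("chr1", 20_000_000)], 2_000_000)


@pytest.fixture(scope="session")
def small_population(small_genome):
    """16 lines on a 10-interval chromosome, deterministic."""
    return simulate_cc_population(16, small_genome, recomb_rate_per_mb=0.05, seed=7)


@pytest.fixture(scope="session")
def small_dosage(small_population):
    return dosage_from_mosaic(small_population, uncertainty=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
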