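import numpy as np
import pytest

from temir import GenomeSimConfig, simulate_genome


@pytest.fixture(scope="session")
def small_genome_sim():
    """A 300-kb genome with 5 intact carriers and 8 shuffled decoys."""
    cfg = GenomeSimConfig(
        genome_length=300_000,
        n_elements=5,
        n_decoys=8,
        element_mutation_rate=0.0,
        rng_seed=3,
    )
    return simulate_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
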