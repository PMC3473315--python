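import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A 120 kb benchmark with 3 planted genes and 2 decoys (seed 7)."""
    from selenoscan.synthetic import GeneratorConfig, simulate
    cfg = GeneratorConfig(genome_length=120_000, n_genes=3, n_pseudogenes=1,
                          n_cys_paralogs=1, n_ests=200, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_coding_model(small_dataset):
    from selenoscan.coding_model import train_markov
    rec = small_dataset.records[0]
    noncoding = [rec.seq[i:i + 2000] for i in range(0, 60_000, 2000)]
    return train_markov(small_dataset.training_cds, noncoding, k=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
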