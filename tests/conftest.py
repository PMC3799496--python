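import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clipsplice import GeneModel, GenomicInterval, SimulationConfig, simulate_genome

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def plus_gene() -> GeneModel:
    """Three exons (0,10), (20,30), (40,50) on the plus strand."""
    return GeneModel(
        "gplus",
        [
            GenomicInterval("chr1", 0, 10, "+"),
            GenomicInterval("chr1", 20, 30, "+"),
            GenomicInterval("chr1", 40, 50, "+"),
        ],
    )


@pytest.fixture
def minus_gene() -> GeneModel:
    """Same exon coordinates on the minus strand (transcript order reversed)."""
    return GeneModel(
        "gminus",
        [
            GenomicInterval("chr1", 40, 50, "-"),
            GenomicInterval("chr1", 20, 30, "-"),
            GenomicInterval("chr1", 0, 10, "-"),
        ],
    )


@pytest.fixture(scope="session")
def small_simulation():
    """A small but complete simulated study shared across tests."""
    config = SimulationConfig(seed=2024, n_genes=40)
    genes, sequences, truth = simulate_genome(config)
    return config, genes, sequences, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
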