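import numpy as np
import pytest
from hypothesis import settings

from tbamkit import SimConfig, make_reference, sample_abundances

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """A small deterministic reference with genes on both strands, rRNA
    regions, and a skewed abundance profile."""
    config = SimConfig(seed=42, n_genes=10, n_samples=2, reads_per_sample=2000)
    genome, genes = make_reference(config)
    abundances = sample_abundances(config)
    return config, genome, genes, abundances


@pytest.fixture(scope="session")
def small_genome(small_world):
    return small_world[1]


@pytest.fixture(scope="session")
def small_genes(small_world):
    return small_world[2]


@pytest.fixture(scope="session")
def small_cds(small_genes):
    return [g for g in small_genes if g.feature_class == "CDS"]


@pytest.fixture(scope="session")
def small_rrna(small_genes):
    return [g for g in small_genes if g.feature_class == "rRNA"]


@pytest.fixture(scope="session")
def small_pool(small_genome, small_cds, small_rrna):
    from tbamkit import design_pool

    return design_pool(small_genome, small_cds, small_rrna)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
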