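import numpy as np
import pytest

from sporeseg.region import RegionSpec, Segment, default_region
from sporeseg.simdata import generate_dataset, generate_parent_pool, sporulate


@pytest.fixture(scope="session")
def region200():
    return default_region(200)


@pytest.fixture(scope="session")
def small_pool():
    """12 distinct alleles over a 60 bp exon/intron/exon amplicon."""
    return generate_parent_pool(12, dominance=0.7, amplicon_length=60, seed=11)


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-noise synthetic dataset: 8 spores from 3 plants, no errors."""
    return generate_dataset(
        n_alleles=15, dominance=0.7, amplicon_length=80,
        nuclei_per_spore=60, reads_per_spore=150,
        sub_rate=0.0, homopolymer_err=0.0, chimera_rate=0.0, seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
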