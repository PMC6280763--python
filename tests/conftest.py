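import numpy as np
import pytest

from cageforge import clustering as cl
from cageforge import normalization as nm
from cageforge import synthetic as syn


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic promoterome shared across tests.

    120 promoters (half sharp, half broad) on a 300-kb chromosome with a
    200k-tag library, power-law normalized and clustered.
    """
    genome, truth = syn.generate_genome(n_promoters=120, sharp_fraction=0.5,
                                        chrom_length=300_000, seed=0)
    table = syn.simulate_library(truth, depth_tags=200_000, seed=0)
    normalized = nm.normalize(table)
    clusters = cl.cluster_ctss(normalized)
    return {"genome": genome, "truth": truth, "table": table,
            "normalized": normalized, "clusters": clusters}


@pytest.fixture(scope="session")
def broad_world():
    """Broad-promoter-only world for shape/periodicity analyses."""
    genome, truth = syn.generate_genome(n_promoters=100, sharp_fraction=0.0,
                                        chrom_length=250_000, seed=1)
    table = syn.simulate_library(truth, depth_tags=200_000, seed=1)
    normalized = nm.normalize(table)
    clusters = cl.cluster_ctss(normalized)
    return {"genome": genome, "truth": truth, "table": table,
            "normalized": normalized, "clusters": clusters}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
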