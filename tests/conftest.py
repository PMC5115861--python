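import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import phylosym as ps

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_table():
    """3 OTUs x 4 samples with GreenGenes-style lineages."""
    counts = pd.DataFrame(
        [[3, 0, 5, 1], [1, 2, 0, 4], [2, 2, 2, 2]],
        index=["OTU1", "OTU2", "OTU3"],
        columns=["s1", "s2", "s3", "s4"],
        dtype=float,
    )
    taxonomy = {
        "OTU1": "k__Bacteria; p__Proteobacteria; c__Alpha; o__Rhodospirillales; f__Acetobacteraceae; g__Acetobacter",
        "OTU2": "k__Bacteria; p__Proteobacteria; c__Alpha; o__Rickettsiales; f__Anaplasmataceae; g__Wolbachia",
        "OTU3": "k__Bacteria; p__Firmicutes; c__Clostridia",
    }
    return ps.OtuTable(counts, taxonomy)


@pytest.fixture
def small_metadata():
    return ps.SampleMetadata(
        sample_species={"s1": "spA", "s2": "spA", "s3": "spB", "s4": "spB"},
        species_clade={"spA": "clade_1", "spB": "clade_1"},
    )


@pytest.fixture
def host6():
    """The fixed six-species reference host phylogeny."""
    return ps.reference_host_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_otu_table(rng, n_otus=None, n_samples=None, with_taxonomy=None):
    """Generate a random valid OtuTable (used by round-trip property tests)."""
    n_otus = n_otus or int(rng.integers(1, 12))
    n_samples = n_samples or int(rng.integers(1, 6))
    counts = rng.integers(0, 50, size=(n_otus, n_samples)).astype(float)
    otus = [f"OTU{i}" for i in range(n_otus)]
    samples = [f"s{i}" for i in range(n_samples)]
    taxonomy = None
    if with_taxonomy if with_taxonomy is not None else rng.random() < 0.5:
        taxonomy = {
            o: f"k__Bacteria; p__P{int(rng.integers(3))}; c__C{int(rng.integers(3))}"
            for o in otus
            if rng.random() < 0.8
        }
    return ps.OtuTable(pd.DataFrame(counts, index=otus, columns=samples), taxonomy or None)
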