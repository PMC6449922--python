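import numpy as np
import pytest

from m2f.simulate import PanGenomeModel, simulate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A small seeded corpus reused by extraction/clustering/pipeline tests.

    Short genes keep the all-vs-all protein searches fast; the marker genes
    (16S array, MLSA set) are full-length.
    """
    model = PanGenomeModel(
        seed=1234,
        n_artifact_prob=0.05,
        gene_length_range=(90, 300),
        rrna_copy_range=(1, 4),
    )
    return simulate_corpus(model, pairs_per_stratum=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
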