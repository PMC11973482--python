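import numpy as np
import pytest

from liquidma import GeneAnnotation, Genome, synthesize_genome


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def small_genome():
    """A 3 kb synthetic genome with ~50% coding, both strands represented."""
    genome, annotation = synthesize_genome(
        length=3000, gc_fraction=0.5, coding_fraction=0.5,
        mean_gene_length=300, seed=11)
    return genome, annotation


@pytest.fixture
def single_cds_genome():
    """Minimal genome: one forward-strand CDS ATG GCT TAA with flanks."""
    seq = "TTTTT" + "ATGGCTTAA" + "TTTTT"
    from liquidma import Gene
    return Genome(seq), GeneAnnotation([Gene(6, 14, "+")])
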