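import numpy as np
import pytest

from xlinkscape import GenomicInterval, SimConfig, TranscriptModel
from xlinkscape.synthetic_data import simulate_study


@pytest.fixture(scope="session")
def two_gene_annotation():
    """A hand-built two-gene annotation: one plus-strand gene with an
    intron, one minus-strand gene, on the same chromosome."""
    a = TranscriptModel(
        "geneA", "chrT", "+",
        {
            "five_utr": [GenomicInterval("chrT", 100, 150, "+")],
            "cds": [GenomicInterval("chrT", 150, 300, "+"),
                    GenomicInterval("chrT", 360, 500, "+")],
            "intron": [GenomicInterval("chrT", 300, 360, "+")],
            "three_utr": [GenomicInterval("chrT", 500, 600, "+")],
        },
    )
    b = TranscriptModel(
        "geneB", "chrT", "-",
        {
            "three_utr": [GenomicInterval("chrT", 700, 800, "-")],
            "cds": [GenomicInterval("chrT", 800, 1000, "-")],
            "five_utr": [GenomicInterval("chrT", 1000, 1050, "-")],
        },
    )
    return {"geneA": a, "geneB": b}


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by read-level tests (WT only)."""
    config = SimConfig(seed=42, n_genes=20, conditions=("WT",), replicates=2,
                       gparclip_depth=4000, mrnaseq_depth=8000)
    genome, transcripts, truth, libraries = simulate_study(config)
    return {
        "config": config,
        "genome": genome,
        "transcripts": transcripts,
        "truth": truth,
        "libraries": libraries,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
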