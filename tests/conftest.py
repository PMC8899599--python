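import numpy as np
import pytest

from meripkit.intervals import GenomicInterval, TranscriptModel
from meripkit.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def plus_transcript():
    """Single-exon plus-strand transcript: 5'UTR 100, CDS 300, 3'UTR 200,
    on contig positions [50, 650)."""
    return TranscriptModel(
        "txP", "gP", "chrP", "+",
        (GenomicInterval("chrP", 50, 650, "+"),),
        cds_start=150, cds_end=450)


@pytest.fixture
def minus_transcript():
    """Single-exon minus-strand transcript with the same anatomy; the TSS
    is the highest genomic coordinate."""
    return TranscriptModel(
        "txM", "gM", "chrM", "-",
        (GenomicInterval("chrM", 50, 650, "-"),),
        cds_start=250, cds_end=550)


@pytest.fixture
def multiexon_transcript():
    """Three-exon plus-strand transcript (exon lengths 200/300/100),
    CDS from spliced 100 to 399."""
    exons = (GenomicInterval("chrX", 100, 300, "+"),
             GenomicInterval("chrX", 500, 800, "+"),
             GenomicInterval("chrX", 1000, 1100, "+"))
    # spliced 100 -> genomic 200; spliced 399 -> genomic 699
    return TranscriptModel("txE", "gE", "chrX", "+", exons,
                           cds_start=200, cds_end=700)


@pytest.fixture
def small_sim_config():
    """A down-scaled simulated experiment that still exercises every stage."""
    return SimulationConfig(n_transcripts=16, n_m6a_sites=6, n_pairs=2,
                            reads_per_site_window=80.0, seed=7)
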