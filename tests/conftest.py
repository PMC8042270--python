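import numpy as np
import pytest
from hypothesis import settings

from mexh.genome_io import Gene, GeneAnnotation, Genome, GenomicInterval, Transcript
from mexh.read_model import SplicedAlignment, UnmappedRead
from mexh.simulate import SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def toy_genome():
    """One contig with a hand-built plus-strand gene and a minus-strand gene.

    Plus gene g1: exon1 [100,200), intron GT..AG, exon2 [300,400);
    CDS [150,200)+[300,350). Minus gene g2: exons [600,700) and [800,900)
    (transcribed right to left), forward-strand intron motif CT..AC.
    """
    rng = np.random.default_rng(42)
    seq = list(_rand_seq(rng, 1000))
    seq[200:202] = "GT"
    seq[298:300] = "AG"
    # minus-strand intron between [700, 800): forward CT..AC
    seq[700:702] = "CT"
    seq[798:800] = "AC"
    genome = Genome({"c1": "".join(seq)})
    g1 = Gene(
        "g1",
        GenomicInterval("c1", 100, 400, "+"),
        "protein_coding",
        (
            Transcript(
                "g1.t1",
                (GenomicInterval("c1", 100, 200, "+"),
                 GenomicInterval("c1", 300, 400, "+")),
                (GenomicInterval("c1", 150, 200, "+"),
                 GenomicInterval("c1", 300, 350, "+")),
            ),
        ),
    )
    g2 = Gene(
        "g2",
        GenomicInterval("c1", 600, 900, "-"),
        "lncRNA",
        (
            Transcript(
                "g2.t1",
                (GenomicInterval("c1", 600, 700, "-"),
                 GenomicInterval("c1", 800, 900, "-")),
            ),
        ),
    )
    return genome, GeneAnnotation((g1, g2))


@pytest.fixture(scope="session")
def small_dataset():
    """Ten genes, six planted microexons spanning the 3-30 nt range."""
    cfg = SimConfig(
        seed=1, n_genes=10, n_microexons=6, coverage=30.0,
        microexon_lengths=(3, 5, 7, 12, 21, 30),
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def discovery(small_dataset):
    from mexh.pipeline import run_discovery

    genome, annotation, truth, reads, mapped, masked = small_dataset
    primary = [
        SplicedAlignment(r.read_id, r.contig, r.strand, r.blocks, sample=r.sample)
        for r in mapped
    ]
    unmapped = [UnmappedRead(r.read_id, r.sequence) for r in masked]
    return run_discovery(genome, annotation, primary, unmapped, max_cycles=3)


def primary_alignments(mapped):
    return [
        SplicedAlignment(r.read_id, r.contig, r.strand, r.blocks, sample=r.sample)
        for r in mapped
    ]


def unmapped_pool(masked):
    return [UnmappedRead(r.read_id, r.sequence) for r in masked]
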