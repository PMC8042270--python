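"""Hand-built fixtures and independent brute-force oracles for placement tests."""

import numpy as np

from mexh.genome_io import (
    Gene,
    GeneAnnotation,
    Genome,
    GenomicInterval,
    Transcript,
    reverse_complement,
)


def rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def microexon_gene(seed=0, me_len=5, exon_len=120, intron_len=60):
    """A plus-strand gene exonA-[intron]-ME-[intron]-exonB on one contig.

    Only the skip-form transcript (exonA, exonB) is annotated, so both
    microexon junctions are novel. Returns (genome, annotation, layout dict).
    """
    rng = np.random.default_rng(seed)
    pad = 200
    exon_a = rand_seq(rng, exon_len)
    exon_b = rand_seq(rng, exon_len)
    i1 = "GT" + rand_seq(rng, intron_len - 4) + "AG"
    i2 = "GT" + rand_seq(rng, intron_len - 4) + "AG"
    for _ in range(100):
        me = rand_seq(rng, me_len)
        if me[3:5] == "GT" or me[:2] == "GT":  # avoid internal donor motifs
            continue
        seq = rand_seq(rng, pad) + exon_a + i1 + me + i2 + exon_b + rand_seq(rng, pad)
        if seq.count("AG" + me + "GT") == 1:  # planted context must be unique
            break
    else:
        raise RuntimeError("could not plant a unique microexon")
    a_start = pad
    a_end = a_start + exon_len
    me_start = a_end + intron_len
    me_end = me_start + me_len
    b_start = me_end + intron_len
    b_end = b_start + exon_len
    genome = Genome({"c1": seq})
    gene = Gene(
        "gX",
        GenomicInterval("c1", a_start, b_end, "+"),
        "protein_coding",
        (
            Transcript(
                "gX.t1",
                (
                    GenomicInterval("c1", a_start, a_end, "+"),
                    GenomicInterval("c1", b_start, b_end, "+"),
                ),
            ),
        ),
    )
    layout = dict(
        a_start=a_start, a_end=a_end, me_start=me_start, me_end=me_end,
        b_start=b_start, b_end=b_end, me_seq=me,
    )
    return genome, GeneAnnotation((gene,)), layout


# Independent brute-force oracle for cut-segment placement -------------------

_ACC = {"+": "AG", "-": "AC"}  # forward-genome dinucleotide 5' of the exon
_DON = {"+": "GT", "-": "CT"}  # forward-genome dinucleotide 3' of the exon


def brute_force_segment_scan(
    genome, gene_span, trunk_blocks, orient, side, segment,
    min_gap=20, max_gap=10_000,
):
    """Every qualifying segment start, by scanning all offsets one by one."""
    cs = genome.contigs[gene_span.contig]
    strand = gene_span.strand
    m = len(segment)
    fwd_seg = segment if orient == "+" else reverse_complement(segment)
    left_side = (side == "five_prime") == (orient == "+")
    trunk_start, trunk_end = trunk_blocks[0][0], trunk_blocks[-1][1]
    # Trunk-adjacent end of the bridging intron must be canonical.
    if left_side and cs[trunk_start - 2 : trunk_start] != _ACC[strand]:
        return []
    if not left_side and cs[trunk_end : trunk_end + 2] != _DON[strand]:
        return []
    hits = []
    for p in range(0, len(cs) - m + 1):
        if cs[p : p + m] != fwd_seg:
            continue
        if cs[p - 2 : p] != _ACC[strand] or cs[p + m : p + m + 2] != _DON[strand]:
            continue
        if p < gene_span.start or p + m > gene_span.end:
            continue
        gap = trunk_start - (p + m) if left_side else p - trunk_end
        if not min_gap <= gap <= max_gap:
            continue
        hits.append(p)
    return hits
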