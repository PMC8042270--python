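"""Spliced-alignment parsing and junction-read classification.

A junction read is a read whose alignment spans at least one intron (an ``N``
CIGAR gap of >= 20 nt). Multi-junction reads span two or more introns; their
interior aligned blocks ("middle junction parts") are exon sequences contained
entirely within the read, which is what makes them microexon evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from .genome_io import Genome, GenomicInterval

#: Minimum intron length; also the lower gap bound for cut-segment placement.
MIN_INTRON = 20

SOURCE_PRIMARY = "primary_mapper"
SOURCE_CUTEND = "cutend_recovered"

SINGLE_JUNCTION = "single_junction"
MULTI_JUNCTION = "multi_junction"
UNSPLICED = "unspliced"

END_PART = "end_part"
MIDDLE_PART = "middle_part"


@dataclass(frozen=True)
class Junction:
    """An intron implied by two adjacent aligned blocks."""

    contig: str
    donor: int      # end of the upstream block (gap start, 0-based)
    acceptor: int   # start of the downstream block (gap end)
    strand: str
    motif: str | None = None  # first 2 + last 2 intron nt, forward genome

    def __post_init__(self) -> None:
        if self.acceptor - self.donor < MIN_INTRON:
            raise ValueError(
                f"junction gap {self.acceptor - self.donor} < {MIN_INTRON}"
            )

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.contig, self.strand, self.donor, self.acceptor)


@dataclass(frozen=True)
class SplicedAlignment:
    read_id: str
    contig: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    mismatches: int = 0
    source: str = SOURCE_PRIMARY
    sample: str | None = None

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.blocks:
            if end <= start:
                raise ValueError(f"{self.read_id}: empty block {start}-{end}")
            if prev_end is not None and start - prev_end < MIN_INTRON:
                raise ValueError(
                    f"{self.read_id}: inter-block gap {start - prev_end} "
                    f"< {MIN_INTRON}"
                )
            prev_end = end

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def n_junctions(self) -> int:
        return len(self.blocks) - 1

    def junctions(self, genome: Genome | None = None) -> list[Junction]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.blocks, self.blocks[1:]):
            motif = None
            if genome is not None:
                seq = genome.contigs[self.contig]
                motif = seq[e0 : e0 + 2] + seq[s1 - 2 : s1]
            out.append(Junction(self.contig, e0, s1, self.strand, motif))
        return out

    def junction_keys(self) -> list[tuple[str, str, int, int]]:
        return [j.key for j in self.junctions()]


@dataclass(frozen=True)
class JunctionPart:
    read_id: str
    interval: GenomicInterval
    position_class: str  # END_PART or MIDDLE_PART
    length: int


@dataclass(frozen=True)
class UnmappedRead:
    read_id: str
    sequence: str
    quality: str | None = None


def classify_junction_read(aln: SplicedAlignment) -> str:
    if len(aln.blocks) >= 3:
        return MULTI_JUNCTION
    if len(aln.blocks) == 2:
        return SINGLE_JUNCTION
    return UNSPLICED


def junction_parts(aln: SplicedAlignment) -> list[JunctionPart]:
    """Split a junction read into its end and middle parts."""
    if aln.n_junctions < 1:
        raise ValueError(f"{aln.read_id} has no junctions")
    parts = []
    last = len(aln.blocks) - 1
    for i, (start, end) in enumerate(aln.blocks):
        cls = MIDDLE_PART if 0 < i < last else END_PART
        iv = GenomicInterval(aln.contig, start, end, aln.strand)
        parts.append(JunctionPart(aln.read_id, iv, cls, end - start))
    return parts


def _blocks_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Aligned reference blocks, splitting only at N; M/=/X/D extend a block."""
    blocks: list[tuple[int, int]] = []
    cur_start, cur = pos, pos
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            cur += length
        elif op == 3:  # N: intron
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
        # I (1) and S (4) consume only the query
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return tuple(blocks)


def _infer_strand(
    read: pysam.AlignedSegment,
    blocks: tuple[tuple[int, int], ...],
    genome: Genome | None,
    library_type: str,
) -> str:
    if genome is not None and len(blocks) > 1:
        seq = genome.contigs[read.reference_name]
        e0, s1 = blocks[0][1], blocks[1][0]
        motif = seq[e0 : e0 + 2] + seq[s1 - 2 : s1]
        if motif == "GTAG":
            return "+"
        if motif == "CTAC":
            return "-"
    if library_type == "fr-firststrand" and read.is_paired:
        # First-in-pair is antisense to the transcript.
        antisense = read.is_read1
        aligned_minus = read.is_reverse
        return "-" if antisense != aligned_minus else "+"
    return "-" if read.is_reverse else "+"


def parse_alignments(
    path,
    genome: Genome | None = None,
    library_type: str = "fr-firststrand",
    sample: str | None = None,
) -> tuple[list[SplicedAlignment], list[UnmappedRead]]:
    """Read a SAM/BAM file into spliced alignments plus the unmapped pool.

    Secondary and supplementary records are ignored. Unmapped records must
    carry their sequence (they feed the cut-end remapper).
    """
    alignments: list[SplicedAlignment] = []
    unmapped: list[UnmappedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_secondary or read.is_supplementary:
                continue
            if read.is_unmapped:
                if not read.query_sequence:
                    raise ValueError(
                        f"unmapped record {read.query_name} has no sequence"
                    )
                qual = (
                    "".join(chr(q + 33) for q in read.query_qualities)
                    if read.query_qualities is not None
                    else None
                )
                unmapped.append(
                    UnmappedRead(read.query_name, read.query_sequence, qual)
                )
                continue
            blocks = _blocks_from_cigar(read.reference_start, read.cigartuples)
            strand = _infer_strand(read, blocks, genome, library_type)
            nm = read.get_tag("NM") if read.has_tag("NM") else 0
            alignments.append(
                SplicedAlignment(
                    read.query_name,
                    read.reference_name,
                    strand,
                    blocks,
                    mismatches=nm,
                    source=SOURCE_PRIMARY,
                    sample=sample,
                )
            )
    return alignments, unmapped


def collect_junction_keys(
    alignments,
) -> set[tuple[str, str, int, int]]:
    keys: set[tuple[str, str, int, int]] = set()
    for aln in alignments:
        keys.update(aln.junction_keys())
    return keys
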