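"""Cut-end read recovery: the core microexon-mapping engine.

Reads left unmapped by a primary spliced aligner frequently fail because a
short (3-7 nt) exonic segment at one end, or a <= 30 nt microexon in the
middle, cannot be anchored. This module recovers such reads:

1. *Derivative generation* — cut 3..7 nt off either end of an unmapped read,
   producing up to 10 derivative reads (trunk + cut segment).
2. *Trunk placement* — an exact-match (0 mismatch) spliced placement of the
   trunk, allowing introns across annotated/previously-recovered junctions or
   de novo canonical GT..AG gaps of 20-10,000 nt, with >= 8 nt terminal
   anchors (shorter terminal blocks only across known junctions).
3. *Segment placement* — scan the genomic window on the cut side of the trunk
   for an exact copy of the segment flanked by AG (upstream) and GT
   (downstream) on the transcribed strand, at a gap of 20-10,000 nt inside
   the host gene span; only uniquely placeable segments are kept.
4. *Cycling* — junctions of recovered reads feed back into the known-junction
   set, so reads that depend on a newly discovered microexon junction are
   recovered in a later cycle. Recovery counts drop to zero within a few
   cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genome_io import Genome, GeneAnnotation, GenomicInterval, reverse_complement
from .read_model import (
    MIN_INTRON,
    SOURCE_CUTEND,
    SplicedAlignment,
    UnmappedRead,
)

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

DEFAULT_CUT_LENGTHS = (3, 4, 5, 6, 7)
DEFAULT_MIN_TRUNK = 16  # cut length + two 8 nt anchors
DEFAULT_ANCHOR = 8
DEFAULT_MIN_GAP = 20
DEFAULT_MAX_GAP = 10_000
DEFAULT_MAX_CYCLES = 3
_SEED = 8  # k-mer size of the genome index

# Forward-genome intron boundary dinucleotides by transcribed strand.
_DONOR_MOTIF = {"+": "GT", "-": "CT"}
_ACCEPTOR_MOTIF = {"+": "AG", "-": "AC"}


@dataclass(frozen=True)
class CutEndRead:
    """A derivative of an unmapped read: the trunk plus the cut segment."""

    parent_id: str
    side: str  # FIVE_PRIME or THREE_PRIME
    k: int
    trunk: str
    segment: str

    def __post_init__(self) -> None:
        if self.side not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"bad cut side {self.side!r}")
        if len(self.segment) != self.k:
            raise ValueError("segment length does not match k")


@dataclass(frozen=True)
class Placement:
    """An exact spliced placement of a sequence on the forward genome.

    ``strand`` is the transcribed strand implied by the junction motifs; for
    a contiguous (junction-free) placement it degenerates to the match
    orientation. ``orient`` records whether the query matched the forward
    genome as-is ('+') or reverse-complemented ('-').
    """

    contig: str
    strand: str
    orient: str
    blocks: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class TrunkPlacement:
    cut_read: CutEndRead
    contig: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    orient: str = "+"
    mismatches: int = 0

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.blocks[0][0], self.blocks[-1][1], self.strand
        )


@dataclass(frozen=True)
class SegmentPlacement:
    interval: GenomicInterval
    upstream_flank: str   # transcribed-strand dinucleotide 5' of the segment
    downstream_flank: str
    gap: int              # intron length between trunk terminus and segment
    within_gene: bool
    unique: bool


def generate_derivatives(
    sequence: str,
    parent_id: str = "read",
    cut_lengths: tuple[int, ...] = DEFAULT_CUT_LENGTHS,
    min_trunk: int = DEFAULT_MIN_TRUNK,
) -> list[CutEndRead]:
    """All admissible cut-end derivatives of an unmapped read.

    One derivative per (side, k) with k in *cut_lengths*; derivatives whose
    trunk would be shorter than *min_trunk* are omitted, so a read of >= 23 nt
    yields the full complement of 10.
    """
    if not sequence:
        raise ValueError("empty read sequence")
    out = []
    for k in cut_lengths:
        if len(sequence) - k < min_trunk:
            continue
        out.append(
            CutEndRead(parent_id, FIVE_PRIME, k, sequence[k:], sequence[:k])
        )
        out.append(
            CutEndRead(parent_id, THREE_PRIME, k, sequence[:-k], sequence[-k:])
        )
    return out


def _match_len(contig_seq: str, pos: int, query: str) -> int:
    """Length of the exact match of *query* against the genome at *pos*."""
    n = len(query)
    limit = min(n, len(contig_seq) - pos)
    if limit == n and contig_seq[pos : pos + n] == query:
        return n
    lo = 0
    step = 16
    while lo < limit:
        hi = min(lo + step, limit)
        if contig_seq[pos + lo : pos + hi] == query[lo:hi]:
            lo = hi
            continue
        while lo < hi and contig_seq[pos + lo] == query[lo]:
            lo += 1
        return lo
    return lo


class GenomeIndex:
    """Exact k-mer index over all contigs (k = 8)."""

    def __init__(self, genome: Genome, k: int = _SEED):
        self.k = k
        self.genome = genome
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.contigs.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((name, i))

    def occurrences(self, prefix: str) -> list[tuple[str, int]]:
        """Genome positions whose k-mer equals the first k nt of *prefix*."""
        if len(prefix) < self.k:
            # Rare (short queries): fall back to a direct scan.
            hits = []
            for name, seq in self.genome.contigs.items():
                start = seq.find(prefix)
                while start != -1:
                    hits.append((name, start))
                    start = seq.find(prefix, start + 1)
            return hits
        return self._index.get(prefix[: self.k], [])


class SplicedPlacer:
    """Exact-match spliced placement of a sequence on a desk-scale genome.

    Every aligned block matches the genome with zero mismatches. Introns are
    either *known* junctions (annotated, or discovered in an earlier recovery
    cycle; exempt from the gap bounds) or de novo gaps of ``min_gap..max_gap``
    nt with the canonical GT..AG motif on the transcribed strand. Terminal
    blocks must reach the anchor length unless they sit on a known junction;
    middle blocks may be arbitrarily short (a contained microexon) provided
    both of their introns qualify.
    """

    def __init__(
        self,
        genome: Genome,
        known_junctions: set[tuple[str, str, int, int]] | None = None,
        anchor: int = DEFAULT_ANCHOR,
        min_gap: int = DEFAULT_MIN_GAP,
        max_gap: int = DEFAULT_MAX_GAP,
        max_junctions: int = 3,
        index: GenomeIndex | None = None,
    ):
        self.genome = genome
        self.anchor = anchor
        self.min_gap = max(min_gap, MIN_INTRON)
        self.max_gap = max_gap
        self.max_junctions = max_junctions
        self.index = index if index is not None else GenomeIndex(genome)
        self.known: set[tuple[str, str, int, int]] = set()
        self._by_donor: dict[tuple[str, str, int], list[int]] = {}
        self._by_strand: dict[str, list[tuple[str, int, int]]] = {"+": [], "-": []}
        if known_junctions:
            self.add_junctions(known_junctions)

    def add_junctions(self, keys) -> None:
        for key in keys:
            if key in self.known:
                continue
            contig, strand, donor, acceptor = key
            self.known.add(key)
            self._by_donor.setdefault((contig, strand, donor), []).append(acceptor)
            self._by_strand[strand].append((contig, donor, acceptor))

    # -- public API ---------------------------------------------------------

    def place(self, sequence: str) -> list[Placement]:
        """All admissible placements of *sequence*.

        Both match orientations are tried, and for each the junctions are
        validated against either transcribed strand's motif/junction set (a
        read's sequencing orientation does not determine its transcript
        strand). Contiguous duplicates across the two motif sets collapse.
        """
        found: set[Placement] = set()
        for orient in "+-":
            q = sequence if orient == "+" else reverse_complement(sequence)
            for ts in "+-":
                for contig, blocks in self._place_oriented(q, ts):
                    strand = ts if len(blocks) > 1 else orient
                    found.add(Placement(contig, strand, orient, tuple(blocks)))
        return sorted(found, key=lambda p: (p.contig, p.strand, p.blocks))

    # -- internals ----------------------------------------------------------

    def _place_oriented(self, q: str, strand: str):
        results: list[tuple[str, list[tuple[int, int]]]] = []
        n = len(q)
        # First block of at least anchor length, found via the k-mer index.
        for contig, p in self.index.occurrences(q):
            cs = self.genome.contigs[contig]
            e = _match_len(cs, p, q)
            if e == n:
                results.append((contig, [(p, p + n)]))
            for first in range(self.anchor, min(e, n - 1) + 1):
                self._extend(
                    q[first:], contig, strand, p + first,
                    [(p, p + first)], 1, results,
                )
        # Short first block resting on a known junction.
        for contig, donor, acceptor in self._by_strand[strand]:
            cs = self.genome.contigs[contig]
            for first in range(1, min(self.anchor, n)):
                start = donor - first
                if start < 0 or cs[start:donor] != q[:first]:
                    continue
                self._extend_at(
                    q[first:], contig, strand, acceptor, True,
                    [(start, donor)], 1, results,
                )
        return results

    def _extend(self, q_rem, contig, strand, prev_end, blocks, depth, results):
        """Enumerate next-block start positions after a junction at prev_end."""
        if depth > self.max_junctions:
            return
        cs = self.genome.contigs[contig]
        m = len(q_rem)
        starts: dict[int, bool] = {}  # start -> junction is known
        for acceptor in self._by_donor.get((contig, strand, prev_end), ()):
            starts[acceptor] = True
        if cs[prev_end : prev_end + 2] == _DONOR_MOTIF[strand]:
            acc = _ACCEPTOR_MOTIF[strand]
            don = _DONOR_MOTIF[strand]
            lo = prev_end + self.min_gap - 2
            hi_start = min(prev_end + self.max_gap, len(cs))
            patterns = []
            if m >= self.anchor:
                # Next block reaches at least the anchor: seed-prefix search.
                patterns.append(acc + q_rem[: min(m, _SEED)])
            # Short de novo middle block (a contained microexon, >= 3 nt):
            # the block is bracketed by an acceptor and the next donor.
            for length in range(3, min(self.anchor, m)):
                patterns.append(acc + q_rem[:length] + don)
            for pat in patterns:
                hi = hi_start - 2 + len(pat)
                pos = cs.find(pat, lo, hi)
                while pos != -1:
                    starts.setdefault(pos + 2, False)
                    pos = cs.find(pat, pos + 1, hi)
        for start, known in starts.items():
            self._extend_at(q_rem, contig, strand, start, known, blocks, depth, results)

    def _extend_at(self, q_rem, contig, strand, start, known, blocks, depth, results):
        cs = self.genome.contigs[contig]
        e = _match_len(cs, start, q_rem)
        m = len(q_rem)
        if e == m and (m >= self.anchor or known):
            results.append((contig, blocks + [(start, start + m)]))
        if depth < self.max_junctions:
            for mid in range(1, min(e, m - 1) + 1):
                self._extend(
                    q_rem[mid:], contig, strand, start + mid,
                    blocks + [(start, start + mid)], depth + 1, results,
                )


class CutEndRemapper:
    """Drives derivative generation, placement and recovery cycles."""

    def __init__(
        self,
        genome: Genome,
        annotation: GeneAnnotation,
        cut_lengths: tuple[int, ...] = DEFAULT_CUT_LENGTHS,
        min_trunk: int = DEFAULT_MIN_TRUNK,
        anchor: int = DEFAULT_ANCHOR,
        min_gap: int = DEFAULT_MIN_GAP,
        max_gap: int = DEFAULT_MAX_GAP,
        max_junctions: int = 3,
        extra_junctions=None,
    ):
        """*extra_junctions*: junction keys already observed by the primary
        mapper (the reconstructed transcriptome the recovery works against)."""
        self.genome = genome
        self.annotation = annotation
        self.cut_lengths = cut_lengths
        self.min_trunk = min_trunk
        self.anchor = anchor
        self.min_gap = max(min_gap, MIN_INTRON)
        self.max_gap = max_gap
        self.placer = SplicedPlacer(
            genome,
            known_junctions=annotation.intron_keys(),
            anchor=anchor,
            min_gap=min_gap,
            max_gap=max_gap,
            max_junctions=max_junctions,
        )
        if extra_junctions:
            self.placer.add_junctions(extra_junctions)
        self.skipped_outside_gene = 0

    # -- trunk and segment placement ---------------------------------------

    def remap_trunk(self, trunk: str) -> list[TrunkPlacement]:
        """Zero-mismatch spliced placements of a trunk (possibly several)."""
        if len(trunk) < self.min_trunk:
            return []
        return [
            TrunkPlacement(None, p.contig, p.strand, p.blocks, p.orient)
            for p in self.placer.place(trunk)
        ]

    def place_cut_segment(
        self, trunk_placement: TrunkPlacement, cut_read: CutEndRead
    ) -> list[SegmentPlacement]:
        """All qualifying genomic homes for the cut segment.

        The scan covers every offset on the segment's side of the trunk
        terminus with a gap of ``min_gap..max_gap`` nt that keeps the segment
        inside the host gene span; a qualifying offset matches the segment
        exactly and carries AG / GT immediately 5' / 3' of the segment on the
        transcribed strand. The ``unique`` flag is true iff exactly one offset
        qualifies.
        """
        contig = trunk_placement.contig
        cs = self.genome.contigs[contig]
        m = cut_read.k
        host = self.annotation.gene_span_containing(trunk_placement.span)
        if host is None:
            self.skipped_outside_gene += 1
            logger.debug(
                "trunk of %s at %s:%d outside any annotated gene; "
                "segment search skipped",
                cut_read.parent_id, contig, trunk_placement.blocks[0][0],
            )
            return []
        # The transcribed strand comes from the host gene (a contiguous trunk
        # carries no motif evidence of its own); a spliced trunk whose
        # junction strand disagrees with the gene cannot host the segment.
        strand = host.span.strand
        if len(trunk_placement.blocks) > 1 and trunk_placement.strand != strand:
            return []
        # The read's cut side in genome coordinates follows the orientation
        # in which the trunk matched the genome.
        left_side = (cut_read.side == FIVE_PRIME) == (trunk_placement.orient == "+")
        fwd_seg = (
            cut_read.segment
            if trunk_placement.orient == "+"
            else reverse_complement(cut_read.segment)
        )
        left_flank = _ACCEPTOR_MOTIF[strand]  # AG 5' of the exon, transcribed
        right_flank = _DONOR_MOTIF[strand]    # GT 3' of the exon, transcribed
        if left_side:
            trunk_edge = trunk_placement.blocks[0][0]
            # Trunk-adjacent end of the bridging intron must also be canonical.
            if cs[trunk_edge - 2 : trunk_edge] != _ACCEPTOR_MOTIF[strand]:
                return []
            lo = max(trunk_edge - self.max_gap - m, host.span.start)
            hi = min(trunk_edge - self.min_gap - m, host.span.end - m)
        else:
            trunk_edge = trunk_placement.blocks[-1][1]
            if cs[trunk_edge : trunk_edge + 2] != _DONOR_MOTIF[strand]:
                return []
            lo = max(trunk_edge + self.min_gap, host.span.start)
            hi = min(trunk_edge + self.max_gap, host.span.end - m)
        placements = []
        pattern = left_flank + fwd_seg + right_flank
        pos = cs.find(pattern, max(lo - 2, 0), hi + 2 + len(pattern))
        while pos != -1:
            seg_start = pos + 2
            if seg_start > hi:
                break
            if seg_start >= lo:
                gap = (
                    trunk_edge - (seg_start + m) if left_side
                    else seg_start - trunk_edge
                )
                if self.min_gap <= gap <= self.max_gap:
                    placements.append(
                        SegmentPlacement(
                            GenomicInterval(contig, seg_start, seg_start + m, strand),
                            "AG", "GT", gap,
                            within_gene=True, unique=False,
                        )
                    )
            pos = cs.find(pattern, pos + 1, hi + 2 + len(pattern))
        if len(placements) == 1:
            placements = [
                SegmentPlacement(
                    p.interval, p.upstream_flank, p.downstream_flank,
                    p.gap, p.within_gene, True,
                )
                for p in placements
            ]
        return placements

    def reconstruct_read(
        self, trunk_placement: TrunkPlacement, segment_placement: SegmentPlacement
    ) -> SplicedAlignment:
        """Recombine a placed trunk and cut segment into one spliced alignment."""
        if not segment_placement.unique:
            raise ValueError("segment placement is not unique")
        seg = segment_placement.interval
        blocks = sorted(
            list(trunk_placement.blocks) + [(seg.start, seg.end)]
        )
        for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
            if s1 < e0:
                raise ValueError(
                    f"segment {seg.start}-{seg.end} overlaps trunk blocks"
                )
        parent = trunk_placement.cut_read.parent_id if trunk_placement.cut_read else "read"
        return SplicedAlignment(
            parent,
            trunk_placement.contig,
            seg.strand,  # transcribed strand of the host gene
            tuple(blocks),
            mismatches=0,
            source=SOURCE_CUTEND,
        )

    # -- read-level recovery -------------------------------------------------

    @staticmethod
    def _select_unique(placements: list[Placement]) -> Placement | None:
        """The unique placement among those with the fewest junctions.

        Mirrors standard aligner behaviour: a contiguous (or less-spliced)
        exact match outranks one that needs extra introns, so a chance
        many-junction chimera cannot veto the parsimonious placement. Ties
        within the minimal class remain ambiguous and are discarded.
        """
        if not placements:
            return None
        fewest = min(len(p.blocks) for p in placements)
        best = [p for p in placements if len(p.blocks) == fewest]
        return best[0] if len(best) == 1 else None

    def recover_read(self, read: UnmappedRead) -> SplicedAlignment | None:
        """Try to recover one unmapped read (direct placement, then cut-end)."""
        placements = self.placer.place(read.sequence)
        chosen = self._select_unique(placements)
        if placements and chosen is None:
            return None  # ambiguous as a whole read: discard
        if chosen is not None:
            return SplicedAlignment(
                read.read_id, chosen.contig, chosen.strand, chosen.blocks,
                mismatches=0, source=SOURCE_CUTEND,
            )
        reconstructions = []
        for d in generate_derivatives(
            read.sequence, read.read_id, self.cut_lengths, self.min_trunk
        ):
            trunk_pl = self._select_unique(self.placer.place(d.trunk))
            if trunk_pl is None:
                continue  # no unique trunk home: discard the derivative
            tp = TrunkPlacement(
                d, trunk_pl.contig, trunk_pl.strand,
                trunk_pl.blocks, trunk_pl.orient,
            )
            segs = self.place_cut_segment(tp, d)
            if len(segs) == 1 and segs[0].unique:
                reconstructions.append(self.reconstruct_read(tp, segs[0]))
        if not reconstructions:
            return None
        first = reconstructions[0]
        same = all(
            (r.contig, r.strand, r.blocks) == (first.contig, first.strand, first.blocks)
            for r in reconstructions
        )
        return first if same else None  # conflicting derivatives: discard

    def run_cycles(
        self, unmapped_reads, max_cycles: int = DEFAULT_MAX_CYCLES
    ) -> tuple[list[SplicedAlignment], list[int]]:
        """Iterate recovery until a cycle recovers nothing or *max_cycles*.

        Junctions of each cycle's recovered alignments become known junctions
        for the next cycle, which is what lets chained reads (a read whose
        trunk needs a junction discovered via another read) come in later.
        """
        pending = list(unmapped_reads)
        recovered: list[SplicedAlignment] = []
        stats: list[int] = []
        for _ in range(max_cycles):
            new, still = [], []
            for read in pending:
                aln = self.recover_read(read)
                (new if aln is not None else still).append(aln or read)
            stats.append(len(new))
            recovered.extend(new)
            keys = set()
            for aln in new:
                keys.update(aln.junction_keys())
            self.placer.add_junctions(keys)
            pending = still
            if not new:
                break
        logger.info("cut-end recovery per cycle: %s (%d left)", stats, len(pending))
        return recovered, stats


# -- thin functional wrappers (the spec's operation surface) -----------------

def remap_trunk(
    genome: Genome, annotation: GeneAnnotation, trunk: str, **params
) -> list[TrunkPlacement]:
    return CutEndRemapper(genome, annotation, **params).remap_trunk(trunk)

def place_cut_segment(
    genome: Genome,
    annotation: GeneAnnotation,
    trunk_placement: TrunkPlacement,
    cut_end_read: CutEndRead,
    **params,
) -> list[SegmentPlacement]:
    return CutEndRemapper(genome, annotation, **params).place_cut_segment(
        trunk_placement, cut_end_read
    )

def reconstruct_read(trunk_placement, segment_placement) -> SplicedAlignment:
    blocks = sorted(
        list(trunk_placement.blocks)
        + [(segment_placement.interval.start, segment_placement.interval.end)]
    )
    if not segment_placement.unique:
        raise ValueError("segment placement is not unique")
    for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
        if s1 < e0:
            raise ValueError("segment overlaps trunk blocks")
    parent = (
        trunk_placement.cut_read.parent_id if trunk_placement.cut_read else "read"
    )
    return SplicedAlignment(
        parent, trunk_placement.contig, segment_placement.interval.strand,
        tuple(blocks), mismatches=0, source=SOURCE_CUTEND,
    )

def run_cycles(
    genome: Genome,
    annotation: GeneAnnotation,
    unmapped_reads,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    **params,
) -> tuple[list[SplicedAlignment], list[int]]:
    return CutEndRemapper(genome, annotation, **params).run_cycles(
        unmapped_reads, max_cycles
    )
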