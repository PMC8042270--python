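"""Synthetic genomes, annotations and reads with planted microexons.

The simulator builds multi-exon genes on a random genome, plants microexons
of known coordinates between two flanking exons (canonical GT..AG introns,
AG/segment/GT context unique within the host gene), emits paired-end reads
from inclusion/skip isoforms at designed per-sample inclusion levels, and
writes a machine-readable truth table.

Instead of running a real spliced aligner, :func:`mask_alignments` applies
the aligner's characteristic failure mode directly: any read whose true
alignment requires placing a short (<= 7 nt by default) exonic segment
across a junction is emitted as unmapped; every other read is emitted as a
correct spliced alignment. This isolates the recovery algorithm from
third-party mapper behaviour while giving it realistic input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .genome_io import (
    Gene,
    GeneAnnotation,
    Genome,
    GenomicInterval,
    Transcript,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))

FR_FIRSTSTRAND = "fr-firststrand"
UNSTRANDED = "unstranded"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    n_microexons: int = 10
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (50, 2000)
    microexon_lengths: tuple[int, ...] | None = None  # sampled 3..30 if None
    samples: tuple[str, ...] = ("s1",)
    sample_groups: dict | None = None  # sample -> group label
    pi_choices: tuple[float, ...] = (0.1, 0.3, 0.5, 0.8, 1.0)
    pi_profiles: tuple[dict, ...] | None = None  # per microexon: sample -> pi
    read_length: int = 100
    library_type: str = FR_FIRSTSTRAND
    fragment_mean: float = 250.0
    fragment_sd: float = 30.0
    coverage: float = 30.0
    error_rate: float = 0.0
    novel_fraction: float = 0.4
    mask_max_segment: int = 7
    intergenic_length: tuple[int, int] = (300, 800)
    exons_per_gene: tuple[int, int] = (4, 6)

    def __post_init__(self) -> None:
        if not 20 <= self.intron_length[0] <= self.intron_length[1] <= 10_000:
            raise ValueError("intron lengths must stay within [20, 10000]")
        if self.microexon_lengths is not None:
            bad = [m for m in self.microexon_lengths if not 3 <= m <= 30]
            if bad:
                raise ValueError(f"microexon lengths outside 3-30: {bad}")
        if self.library_type not in (FR_FIRSTSTRAND, UNSTRANDED):
            raise ValueError(f"unknown library type {self.library_type!r}")
        if self.fragment_mean < self.read_length:
            raise ValueError("fragment size must be >= read length")


@dataclass
class TruthMicroexon:
    me_id: str
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    length: int
    annotated: bool
    pi: dict  # sample -> designed inclusion level
    designed_label: str  # CS / AS / unobserved
    # Filled in once reads exist:
    expected_total: int = 0
    expected_unique: int = 0
    expected_multi: int = 0
    expected_min_flank: int | None = None
    expected_counts: dict = field(default_factory=dict)
    # expected_counts[sample] = (inclusion_left, inclusion_right, skip)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.strand)


@dataclass
class TruthTable:
    microexons: list[TruthMicroexon]
    expected_cycles: list[int] = field(default_factory=list)

    def by_key(self) -> dict:
        return {m.key: m for m in self.microexons}

    def to_frame(self):
        import pandas as pd

        rows = []
        for m in self.microexons:
            row = {
                "me_id": m.me_id, "gene_id": m.gene_id, "contig": m.contig,
                "start": m.start, "end": m.end, "strand": m.strand,
                "length": m.length, "annotated": m.annotated,
                "designed_label": m.designed_label,
                "expected_total": m.expected_total,
                "expected_unique": m.expected_unique,
                "expected_multi": m.expected_multi,
                "expected_min_flank": m.expected_min_flank,
            }
            for sample, pi in m.pi.items():
                row[f"pi_{sample}"] = pi
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimRead:
    """One sequenced mate with its true genomic placement."""

    read_id: str
    sample: str
    sequence: str  # as sequenced
    contig: str
    strand: str  # transcribed strand of the source gene
    blocks: tuple[tuple[int, int], ...]
    reverse: bool  # sequenced sequence is the reverse complement of the genome
    from_inclusion: bool
    gene_id: str
    n_errors: int = 0


@dataclass
class _SimGene:
    gene_id: str
    strand: str
    exons: list[GenomicInterval]         # normal exons, genomic order
    microexon: GenomicInterval | None
    me_slot: int | None                  # microexon sits between exon slot-1 and slot
    annotated_me: bool


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


class Simulator:
    def __init__(self, config: SimConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.genome: Genome | None = None
        self.annotation: GeneAnnotation | None = None
        self.truth: TruthTable | None = None
        self._genes: list[_SimGene] = []

    # -- genome & annotation -------------------------------------------------

    def make_genome_annotation(self) -> tuple[Genome, GeneAnnotation, TruthTable]:
        cfg, rng = self.config, self.rng
        me_lengths = list(
            cfg.microexon_lengths
            if cfg.microexon_lengths is not None
            else rng.integers(3, 31, size=cfg.n_microexons)
        )
        if len(me_lengths) > cfg.n_genes:
            raise ValueError("more microexons than genes")
        host_genes = rng.choice(cfg.n_genes, size=len(me_lengths), replace=False)
        me_of_gene = dict(zip(host_genes.tolist(), me_lengths))
        novel = rng.random(len(me_lengths)) < cfg.novel_fraction

        chunks: list[str] = []
        pos = 0
        genes: list[Gene] = []
        truth_mes: list[TruthMicroexon] = []
        me_idx = 0
        for gi in range(cfg.n_genes):
            pad = int(rng.integers(*cfg.intergenic_length))
            chunks.append(_random_seq(rng, pad))
            pos += pad
            me_len = me_of_gene.get(gi)
            sim_gene, gene_seq, me_truth_info = self._build_gene(
                f"g{gi:03d}", pos, me_len
            )
            chunks.append(gene_seq)
            pos += len(gene_seq)
            if me_len is not None:
                sim_gene.annotated_me = not bool(novel[me_idx])
            self._genes.append(sim_gene)
            genes.append(self._annotate_gene(sim_gene))
            if me_len is not None:
                me = sim_gene.microexon
                pi = self._design_pi(me_idx)
                truth_mes.append(
                    TruthMicroexon(
                        f"me{me_idx:03d}", sim_gene.gene_id, "chr1",
                        me.start, me.end, me.strand, len(me),
                        sim_gene.annotated_me, pi, _designed_label(pi),
                    )
                )
                me_idx += 1
        chunks.append(_random_seq(rng, int(rng.integers(*cfg.intergenic_length))))
        self.genome = Genome({"chr1": "".join(chunks)})
        self.annotation = GeneAnnotation(tuple(genes))
        self.truth = TruthTable(truth_mes)
        return self.genome, self.annotation, self.truth

    def _design_pi(self, me_idx: int) -> dict:
        cfg = self.config
        if cfg.pi_profiles is not None:
            return dict(cfg.pi_profiles[me_idx % len(cfg.pi_profiles)])
        pi = float(self.rng.choice(cfg.pi_choices))
        return {s: pi for s in cfg.samples}

    def _build_gene(self, gene_id: str, genome_offset: int, me_len: int | None):
        """Build one gene in transcribed orientation, then place it."""
        cfg, rng = self.config, self.rng
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            for _ in range(n_exons)
        ]
        slot = None
        if me_len is not None:
            slot = int(rng.integers(1, n_exons))  # between exon slot-1 and slot
            # Flanking exons at least one read long, so a read spanning the
            # microexon cannot reach a second junction.
            for j in (slot - 1, slot):
                exon_lens[j] = max(exon_lens[j], cfg.read_length)
        intron_lens = [
            int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
            for _ in range(n_exons - 1 + (2 if me_len is not None else 0))
        ]

        for _ in range(50):
            exon_seqs = [_random_seq(rng, n) for n in exon_lens]
            me_seq = _random_seq(rng, me_len) if me_len is not None else None
            parts, kinds = [], []  # transcribed order
            ii = 0
            for j in range(n_exons):
                parts.append(exon_seqs[j]); kinds.append(("exon", j))
                if j == n_exons - 1:
                    break
                if slot is not None and j == slot - 1:
                    parts.append(_intron(rng, intron_lens[ii])); kinds.append(("intron", None)); ii += 1
                    parts.append(me_seq); kinds.append(("me", None))
                    parts.append(_intron(rng, intron_lens[ii])); kinds.append(("intron", None)); ii += 1
                else:
                    parts.append(_intron(rng, intron_lens[ii])); kinds.append(("intron", None)); ii += 1
            gene_seq = "".join(parts)
            if me_seq is None or _count_overlapping(gene_seq, "AG" + me_seq + "GT") == 1:
                break
        else:
            raise RuntimeError(
                f"{gene_id}: could not plant a unique microexon context"
            )

        # Transcribed offsets -> genomic intervals.
        offsets = []
        off = 0
        for part, kind in zip(parts, kinds):
            offsets.append((off, len(part), kind))
            off += len(part)
        total = off
        if strand == "-":
            gene_seq = reverse_complement(gene_seq)

        def to_genomic(o, n):
            if strand == "+":
                return genome_offset + o, genome_offset + o + n
            return genome_offset + total - (o + n), genome_offset + total - o

        exon_ivs: list[GenomicInterval] = []
        me_iv = None
        for o, n, (kind, j) in offsets:
            s, e = to_genomic(o, n)
            if kind == "exon":
                exon_ivs.append(GenomicInterval("chr1", s, e, strand))
            elif kind == "me":
                me_iv = GenomicInterval("chr1", s, e, strand)
        exon_ivs.sort(key=lambda iv: iv.start)
        return (
            _SimGene(gene_id, strand, exon_ivs, me_iv, slot, True),
            gene_seq,
            None,
        )

    def _annotate_gene(self, g: _SimGene) -> Gene:
        """Skip-form transcript always annotated; inclusion form only when the
        microexon is not withheld as novel."""
        contig = "chr1"
        strand = g.strand
        span = GenomicInterval(
            contig, g.exons[0].start, g.exons[-1].end, strand
        )
        interior = g.exons[1:-1]
        cds = tuple(interior)
        transcripts = [Transcript(f"{g.gene_id}.t1", tuple(g.exons), cds)]
        if g.microexon is not None and g.annotated_me:
            with_me = sorted(g.exons + [g.microexon], key=lambda iv: iv.start)
            cds2 = tuple(
                iv for iv in with_me
                if iv in interior or iv == g.microexon
            ) if _me_in_cds(g) else cds
            transcripts.append(
                Transcript(f"{g.gene_id}.t2", tuple(with_me), cds2)
            )
        return Gene(g.gene_id, span, "protein_coding", tuple(transcripts))

    # -- reads ---------------------------------------------------------------

    def simulate_reads(self) -> list[SimRead]:
        """Paired-end reads for every sample; each mate is one SimRead."""
        cfg, rng = self.config, self.rng
        if self.genome is None:
            raise RuntimeError("call make_genome_annotation first")
        truth_by_gene = {m.gene_id: m for m in self.truth.microexons}
        self._tx_cache: dict[tuple[str, bool], str] = {}
        reads: list[SimRead] = []
        for sample in cfg.samples:
            for g in self._genes:
                skip_chain = _tx_chain(g, include_me=False)
                inc_chain = _tx_chain(g, include_me=True) if g.microexon else None
                tx_len = sum(n for n, _ in skip_chain)
                n_frag = max(1, round(cfg.coverage * tx_len / (2 * cfg.read_length)))
                pi = (
                    truth_by_gene[g.gene_id].pi[sample]
                    if g.gene_id in truth_by_gene else 0.0
                )
                for fi in range(n_frag):
                    inc = bool(g.microexon) and rng.random() < pi
                    chain = inc_chain if inc else skip_chain
                    clen = sum(n for n, _ in chain)
                    flen = int(np.clip(
                        round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)),
                        cfg.read_length, clen,
                    ))
                    start = int(rng.integers(0, clen - flen + 1))
                    reads.extend(
                        self._make_pair(g, chain, sample, fi, start, flen, inc)
                    )
        return reads

    def _make_pair(self, g, chain, sample, fi, start, flen, inc):
        cfg, rng = self.config, self.rng
        cache_key = (g.gene_id, inc)
        tseq = self._tx_cache.get(cache_key)
        if tseq is None:
            tseq = self._tx_seq(chain)
            self._tx_cache[cache_key] = tseq
        frag = tseq[start : start + flen]
        sense_5p = frag[: cfg.read_length]
        sense_3p_rc = reverse_complement(frag[-cfg.read_length :])
        # fr-firststrand: read 1 is antisense to the transcript.
        if cfg.library_type == UNSTRANDED and rng.random() < 0.5:
            mates = [(1, sense_5p, False), (2, sense_3p_rc, True)]
        else:
            mates = [(1, sense_3p_rc, True), (2, sense_5p, False)]
        out = []
        for mate_no, seq, antisense in mates:
            if antisense:
                lo, hi = start + flen - cfg.read_length, start + flen
            else:
                lo, hi = start, start + cfg.read_length
            blocks = _chain_blocks(chain, g.strand, lo, hi)
            seq, n_err = self._with_errors(seq)
            # Forward-genome orientation: sense mates of '+' genes and
            # antisense mates of '-' genes match the forward genome.
            reverse = antisense == (g.strand == "+")
            out.append(
                SimRead(
                    f"{sample}:{g.gene_id}:f{fi}/{mate_no}", sample, seq,
                    "chr1", g.strand, blocks, reverse, inc, g.gene_id, n_err,
                )
            )
        return out

    def _with_errors(self, seq: str) -> tuple[str, int]:
        rate = self.config.error_rate
        if rate <= 0:
            return seq, 0
        chars = list(seq)
        n_err = 0
        hits = np.nonzero(self.rng.random(len(chars)) < rate)[0]
        for i in hits:
            options = [b for b in "ACGT" if b != chars[i]]
            chars[i] = options[int(self.rng.integers(0, 3))]
            n_err += 1
        return "".join(chars), n_err

    def _tx_seq(self, chain) -> str:
        parts = []
        for n, iv in chain:
            parts.append(self.genome.fetch(iv))
        return "".join(parts)


def _me_in_cds(g: _SimGene) -> bool:
    return g.me_slot is not None and 1 <= g.me_slot - 1 and g.me_slot <= len(g.exons) - 2


def _intron(rng, n: int) -> str:
    return "GT" + _random_seq(rng, n - 4) + "AG"


def _count_overlapping(haystack: str, needle: str) -> int:
    count, pos = 0, haystack.find(needle)
    while pos != -1:
        count += 1
        pos = haystack.find(needle, pos + 1)
    return count


def _designed_label(pi: dict) -> str:
    values = list(pi.values())
    if all(v == 1.0 for v in values):
        return "CS"
    if all(v == 0.0 for v in values):
        return "unobserved"
    return "AS"


def _tx_chain(g: _SimGene, include_me: bool):
    """(length, genomic interval) per exon in transcribed order."""
    ivs = list(g.exons)
    if include_me and g.microexon is not None:
        ivs = sorted(ivs + [g.microexon], key=lambda iv: iv.start)
    if g.strand == "-":
        ivs = ivs[::-1]
    return [(len(iv), iv) for iv in ivs]


def _chain_blocks(chain, strand, lo, hi) -> tuple[tuple[int, int], ...]:
    """Map a transcript-coordinate interval [lo, hi) to genomic blocks."""
    blocks = []
    off = 0
    for n, iv in chain:
        s, e = max(lo, off), min(hi, off + n)
        if s < e:
            rs, re = s - off, e - off
            if strand == "+":
                blocks.append((iv.start + rs, iv.start + re))
            else:
                blocks.append((iv.end - re, iv.end - rs))
        off += n
    return tuple(sorted(blocks))


# -- mask policy -------------------------------------------------------------

def mask_alignments(
    reads: list[SimRead], max_segment: int = 7
) -> tuple[list[SimRead], list[SimRead]]:
    """Split reads into (aligned, unmapped) per the short-segment policy.

    A read is unmapped iff its true alignment contains an exonic block of
    <= *max_segment* nt — the segments a seed-and-anchor spliced aligner
    cannot place.
    """
    mapped, masked = [], []
    for read in reads:
        if any(e - s <= max_segment for s, e in read.blocks):
            masked.append(read)
        else:
            mapped.append(read)
    return mapped, masked


def write_sam(reads: list[SimRead], genome: Genome, path) -> None:
    """Write aligned reads as an uncompressed SAM file (NM and XS tags set)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in genome.contigs.items()
        ],
    }
    refs = {name: i for i, name in enumerate(genome.contigs)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            a.flag = 16 if read.reverse else 0
            a.reference_id = refs[read.contig]
            a.reference_start = read.blocks[0][0]
            a.mapping_quality = 50
            cigar = []
            prev_end = None
            for s, e in read.blocks:
                if prev_end is not None:
                    cigar.append(f"{s - prev_end}N")
                cigar.append(f"{e - s}M")
                prev_end = e
            a.cigarstring = "".join(cigar)
            seq = read.sequence
            if read.reverse:
                seq = reverse_complement(seq)
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("NM", read.n_errors)
            a.set_tag("XS", read.strand)
            out.write(a)


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(
                f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n"
            )


def write_truth_tsv(truth: TruthTable, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


# -- expected outcomes -------------------------------------------------------

def finalize_truth(
    truth: TruthTable,
    reads: list[SimRead],
    annotation: GeneAnnotation,
    config: SimConfig,
    anchor: int = 8,
) -> TruthTable:
    """Fill in expected support counts and per-cycle recovery numbers.

    Mirrors the recovery contract on the reads' *true* placements: a masked
    read is recoverable once every short (< anchor) terminal block rests on a
    known junction; a read whose single offending terminal block coincides
    exactly with a planted microexon is recoverable through the cut-end path,
    which is what first publishes that microexon's junction. Reads carrying
    sequencing errors are never recoverable (zero-mismatch contract).
    """
    mapped, masked = mask_alignments(reads, config.mask_max_segment)
    me_keys = {m.key for m in truth.microexons}

    def junctions(read):
        out = []
        for (s0, e0), (s1, e1) in zip(read.blocks, read.blocks[1:]):
            out.append((read.contig, read.strand, e0, s1))
        return out

    # Known set: annotated introns plus everything the primary mapper saw.
    known = set(annotation.intron_keys())
    for read in mapped:
        known.update(junctions(read))

    def offending(read, known_now):
        """Short terminal blocks whose junction is not yet known."""
        bad = []
        b = read.blocks
        if len(b) >= 2:
            if b[0][1] - b[0][0] < anchor and junctions(read)[0] not in known_now:
                bad.append(("first", b[0]))
            if b[-1][1] - b[-1][0] < anchor and junctions(read)[-1] not in known_now:
                bad.append(("last", b[-1]))
        return bad

    recovered: list[SimRead] = []
    pending = [r for r in masked if r.n_errors == 0]
    cycles: list[int] = []
    for _ in range(10):
        new, still = [], []
        for read in pending:
            bad = offending(read, known)
            ok = not bad
            if len(bad) == 1:
                (_, (s, e)) = bad[0]
                if 3 <= e - s <= 7 and (read.contig, s, e, read.strand) in me_keys:
                    ok = True  # cut-end path
            (new if ok else still).append(read)
        cycles.append(len(new))
        for read in new:
            known.update(junctions(read))
        recovered.extend(new)
        pending = still
        if not new:
            break
    truth.expected_cycles = cycles

    final = mapped + recovered
    for me in truth.microexons:
        patterns = set()
        total = multi = 0
        min_flank = None
        for read in final:
            b = read.blocks
            if read.contig != me.contig or read.strand != me.strand:
                continue
            try:
                i = b.index((me.start, me.end))
            except ValueError:
                continue
            if len(b) < 2:
                continue
            total += 1
            patterns.add((read.strand, b))
            if 0 < i < len(b) - 1:
                multi += 1
                flank = min(b[i - 1][1] - b[i - 1][0], b[i + 1][1] - b[i + 1][0])
                min_flank = flank if min_flank is None else min(min_flank, flank)
        me.expected_total = total
        me.expected_unique = len(patterns)
        me.expected_multi = multi
        me.expected_min_flank = min_flank
        # Junction counts feeding PSI, per sample, over the final alignments.
        gene = next(
            g for g in annotation.genes if g.gene_id == me.gene_id
        )
        exons = sorted(
            {e for t in gene.transcripts for e in t.exons}, key=lambda e: e.start
        )
        left = max((e.end for e in exons if e.end <= me.start), default=None)
        right = min((e.start for e in exons if e.start >= me.end), default=None)
        for sample in config.samples:
            inc_l = inc_r = skip = 0
            for read in final:
                if read.sample != sample or read.contig != me.contig:
                    continue
                for j in junctions(read):
                    if left is not None and j[2] == left and j[3] == me.start:
                        inc_l += 1
                    elif right is not None and j[2] == me.end and j[3] == right:
                        inc_r += 1
                    elif (
                        left is not None and right is not None
                        and j[2] == left and j[3] == right
                    ):
                        skip += 1
            me.expected_counts[sample] = (inc_l, inc_r, skip)
    return truth


def expected_call(
    me: TruthMicroexon,
    min_unique: int = 2,
    min_total: int = 3,
    min_flank: int = 8,
    short_max: int = 7,
) -> str:
    """What the caller should conclude for a planted microexon.

    ``absent``: no multi-junction read contains it as a middle part, so no
    candidate can exist; ``candidate``: detected but below the reliability
    thresholds; ``reliable``: meets the applicable conditions for its length.
    """
    if me.expected_multi < 1:
        return "absent"
    ok = (
        me.expected_unique >= min_unique
        and me.expected_total >= min_total
    )
    if me.length <= short_max:
        ok = ok and (me.expected_min_flank or 0) >= min_flank
    return "reliable" if ok else "candidate"


def sample_trio_counts(
    rng: np.random.Generator, pi: float, n_fragments: int
) -> tuple[int, int, int]:
    """Junction counts for one trio event at designed inclusion level *pi*.

    Each junction-spanning fragment reads the inclusion isoform with
    probability *pi*; inclusion reads cross both microexon junctions (the
    exon is far shorter than a read), skip reads cross the direct junction.
    """
    inc = int(rng.binomial(n_fragments, pi))
    return inc, inc, n_fragments - inc


def simulate_dataset(config: SimConfig):
    """End-to-end convenience: genome, annotation, truth, reads, mask split."""
    sim = Simulator(config)
    genome, annotation, truth = sim.make_genome_annotation()
    reads = sim.simulate_reads()
    mapped, masked = mask_alignments(reads, config.mask_max_segment)
    finalize_truth(truth, reads, annotation, config)
    return genome, annotation, truth, reads, mapped, masked
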