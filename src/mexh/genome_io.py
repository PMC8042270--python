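"""Reference genome and gene-annotation I/O.

Internally every coordinate is 0-based half-open on the forward genome strand;
GTF input/output is 1-based inclusive and BED output is 0-based half-open.
Sequence fetches are strand-aware: a minus-strand fetch returns the reverse
complement, i.e. the transcribed sequence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REGION_CDS = "CDS"
REGION_UTR5 = "UTR5"
REGION_UTR3 = "UTR3"
REGION_NONCODING = "noncoding_gene"
REGION_INTERGENIC = "intergenic"

_REGION_PRECEDENCE = {REGION_CDS: 0, REGION_UTR5: 1, REGION_UTR3: 2, REGION_NONCODING: 3}


class FastaError(ValueError):
    """Malformed or empty FASTA record."""


class GtfError(ValueError):
    """Malformed GTF feature or inconsistent gene model."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on one contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Genome:
    """Uppercased contig sequences keyed by contig name."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FastaError(f"contig {name!r} has an empty sequence")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        contigs: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            seq = str(record.seq).upper()
            if not seq:
                raise FastaError(f"record {record.id!r} has an empty sequence")
            if record.id in contigs:
                raise FastaError(f"duplicate contig name {record.id!r}")
            contigs[record.id] = seq
        if not contigs:
            raise FastaError(f"no FASTA records found in {path}")
        return cls(contigs)

    def contig_length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, interval: GenomicInterval) -> str:
        """Return the sequence of *interval*, reverse-complemented for '-'."""
        try:
            seq = self.contigs[interval.contig]
        except KeyError:
            raise KeyError(f"unknown contig {interval.contig!r}") from None
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.contig}:{interval.start}-{interval.end} "
                f"exceeds contig length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise GtfError(f"transcript {self.transcript_id} has no exons")
        contig = self.exons[0].contig
        strand = self.exons[0].strand
        prev_end = -1
        for exon in sorted(self.exons, key=lambda e: e.start):
            if exon.contig != contig or exon.strand != strand:
                raise GtfError(
                    f"transcript {self.transcript_id}: exons on mixed "
                    "contigs or strands"
                )
            if exon.start < prev_end:
                raise GtfError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = exon.end
        object.__setattr__(
            self, "exons", tuple(sorted(self.exons, key=lambda e: e.start))
        )
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise GtfError(
                    f"transcript {self.transcript_id}: CDS "
                    f"{c.start}-{c.end} outside every exon"
                )
        object.__setattr__(
            self, "cds", tuple(sorted(self.cds, key=lambda c: c.start))
        )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.contig, a.end, b.start, self.strand))
        return out


@dataclass(frozen=True)
class Gene:
    gene_id: str
    span: GenomicInterval
    biotype: str
    transcripts: tuple[Transcript, ...]

    @property
    def is_coding(self) -> bool:
        return any(t.cds for t in self.transcripts)


@dataclass(frozen=True)
class GeneAnnotation:
    genes: tuple[Gene, ...]

    def genes_overlapping(self, interval: GenomicInterval) -> list[Gene]:
        return [g for g in self.genes if g.span.overlaps(interval)]

    def gene_span_containing(self, interval: GenomicInterval) -> Gene | None:
        """The gene whose span contains *interval* (the 'gene range')."""
        for g in self.genes:
            if g.span.contains(interval):
                return g
        return None

    def exon_keys(self) -> set[tuple[str, int, int, str]]:
        keys = set()
        for g in self.genes:
            for t in g.transcripts:
                for e in t.exons:
                    keys.add((e.contig, e.start, e.end, e.strand))
        return keys

    def intron_keys(self) -> set[tuple[str, str, int, int]]:
        """Annotated introns as (contig, strand, gap_start, gap_end)."""
        keys = set()
        for g in self.genes:
            for t in g.transcripts:
                for i in t.introns():
                    keys.add((i.contig, i.strand, i.start, i.end))
        return keys

    def internal_exons(self, min_length: int = 0) -> list[tuple[Gene, Transcript, int]]:
        """(gene, transcript, exon index) for exons with neighbours on both sides."""
        out = []
        for g in self.genes:
            for t in g.transcripts:
                for i in range(1, len(t.exons) - 1):
                    if len(t.exons[i]) >= min_length:
                        out.append((g, t, i))
        return out


def load_fasta(path) -> Genome:
    return Genome.from_fasta(path)


def fetch(genome: Genome, interval: GenomicInterval) -> str:
    """Strand-aware sequence fetch (reverse complement for minus intervals)."""
    return genome.fetch(interval)


def load_gtf(path) -> GeneAnnotation:
    """Load gene/transcript/exon/CDS features from a GTF file.

    Transcripts are assembled from exon features grouped by ``transcript_id``;
    gene spans come from gene features when present, otherwise from the union
    of the gene's transcripts.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    cds_by_tx: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        if "transcript_id" not in feat.attributes:
            raise GtfError(
                f"{feat.featuretype} feature at {feat.seqid}:{feat.start} "
                "lacks a transcript_id attribute"
            )
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes.get("gene_id", [tx_id])[0]
        tx_gene[tx_id] = gene_id
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        target = exons_by_tx if feat.featuretype == "exon" else cds_by_tx
        target.setdefault(tx_id, []).append(iv)

    gene_meta: dict[str, tuple[GenomicInterval | None, str]] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        biotype = feat.attributes.get(
            "gene_biotype", feat.attributes.get("gene_type", ["protein_coding"])
        )[0]
        gene_meta[gid] = (
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand),
            biotype,
        )

    tx_by_gene: dict[str, list[Transcript]] = {}
    for tx_id, exons in exons_by_tx.items():
        tx = Transcript(tx_id, tuple(exons), tuple(cds_by_tx.get(tx_id, ())))
        tx_by_gene.setdefault(tx_gene[tx_id], []).append(tx)

    genes = []
    for gid, txs in tx_by_gene.items():
        txs = sorted(txs, key=lambda t: t.transcript_id)
        if gid in gene_meta:
            span, biotype = gene_meta[gid]
        else:
            span = GenomicInterval(
                txs[0].contig,
                min(t.exons[0].start for t in txs),
                max(t.exons[-1].end for t in txs),
                txs[0].strand,
            )
            biotype = "protein_coding" if any(t.cds for t in txs) else "unknown"
        genes.append(Gene(gid, span, biotype, tuple(txs)))
    genes.sort(key=lambda g: (g.span.contig, g.span.start))
    return GeneAnnotation(tuple(genes))


def _gtf_attr(gene: Gene, tx: Transcript | None = None) -> str:
    parts = [f'gene_id "{gene.gene_id}"']
    if tx is not None:
        parts.append(f'transcript_id "{tx.transcript_id}"')
    parts.append(f'gene_biotype "{gene.biotype}"')
    return "; ".join(parts) + ";"


def write_gtf(annotation: GeneAnnotation, path) -> None:
    """Write the annotation back to GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in annotation.genes:
            s = gene.span
            fh.write(
                f"{s.contig}\tmexh\tgene\t{s.start + 1}\t{s.end}\t.\t"
                f"{s.strand}\t.\t{_gtf_attr(gene)}\n"
            )
            for tx in gene.transcripts:
                t0 = tx.exons[0].start
                t1 = tx.exons[-1].end
                fh.write(
                    f"{s.contig}\tmexh\ttranscript\t{t0 + 1}\t{t1}\t.\t"
                    f"{s.strand}\t.\t{_gtf_attr(gene, tx)}\n"
                )
                for e in tx.exons:
                    fh.write(
                        f"{e.contig}\tmexh\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{_gtf_attr(gene, tx)}\n"
                    )
                for c in tx.cds:
                    fh.write(
                        f"{c.contig}\tmexh\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                        f"{c.strand}\t0\t{_gtf_attr(gene, tx)}\n"
                    )


def write_bed(intervals: Iterable[tuple[GenomicInterval, str, float]], path) -> None:
    """Write (interval, name, score) triples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def _flank_label(gene: Gene, exon: GenomicInterval) -> str:
    """Region status of an annotated exon: CDS if any transcript's CDS touches it."""
    for t in gene.transcripts:
        for c in t.cds:
            if exon.overlaps(c):
                return REGION_CDS
    return _utr_side(gene, exon)


def _utr_side(gene: Gene, interval: GenomicInterval) -> str:
    cds_starts = [c.start for t in gene.transcripts for c in t.cds]
    cds_ends = [c.end for t in gene.transcripts for c in t.cds]
    if not cds_starts:
        return REGION_NONCODING
    cds_lo, cds_hi = min(cds_starts), max(cds_ends)
    if interval.end <= cds_lo:
        return REGION_UTR5 if gene.span.strand == "+" else REGION_UTR3
    if interval.start >= cds_hi:
        return REGION_UTR3 if gene.span.strand == "+" else REGION_UTR5
    return REGION_CDS


def _classify_in_gene(gene: Gene, interval: GenomicInterval) -> str:
    if not gene.is_coding or gene.biotype not in ("protein_coding", "coding"):
        if not gene.is_coding:
            return REGION_NONCODING
    for t in gene.transcripts:
        for c in t.cds:
            if c.contains(interval):
                return REGION_CDS
    for t in gene.transcripts:
        for e in t.exons:
            if e.contains(interval):
                return _utr_side(gene, interval)
    # Intronic at this locus: classify by the flanking annotated exons. A novel
    # interval between two CDS-bearing exons is frame-bearing context, hence CDS.
    exons = sorted(
        {e for t in gene.transcripts for e in t.exons}, key=lambda e: e.start
    )
    left = [e for e in exons if e.end <= interval.start]
    right = [e for e in exons if e.start >= interval.end]
    labels = []
    if left:
        labels.append(_flank_label(gene, max(left, key=lambda e: e.end)))
    if right:
        labels.append(_flank_label(gene, min(right, key=lambda e: e.start)))
    if labels and all(l == REGION_CDS for l in labels):
        return REGION_CDS
    for wanted in (REGION_UTR5, REGION_UTR3):
        if wanted in labels:
            return wanted
    return _utr_side(gene, interval)


def classify_region(annotation: GeneAnnotation, interval: GenomicInterval) -> str:
    """Assign a gene-region label to *interval*.

    Returns one of ``CDS``, ``UTR5``, ``UTR3``, ``noncoding_gene`` or
    ``intergenic``; when overlapping genes disagree the precedence is
    CDS > UTR5 > UTR3 > noncoding_gene.
    """
    labels = [
        _classify_in_gene(g, interval) for g in annotation.genes_overlapping(interval)
    ]
    if not labels:
        return REGION_INTERGENIC
    return min(labels, key=lambda l: _REGION_PRECEDENCE[l])
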