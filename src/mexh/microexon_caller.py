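"""Microexon candidate collection and the four-condition reliability filter.

A candidate is a 3-30 nt exon interval observed as the middle junction part
of at least one multi-junction read. Support is counted over all reads whose
aligned block equals the candidate interval exactly:

* middle parts always count and mark multi-junction support;
* end parts (a read terminating exactly at the exon boundary) count only
  because the interval is already corroborated as a middle part elsewhere.

Reliability: candidates of 8-30 nt need (1) unique junction reads >= 2 and
(2) total junction reads >= 3; candidates of 3-7 nt additionally need (3) at
least one multi-junction read and (4) every supporting multi-junction read's
flanking blocks >= 8 nt.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GeneAnnotation, GenomicInterval, classify_region
from .read_model import SplicedAlignment

MIN_MICROEXON = 3
MAX_MICROEXON = 30
SHORT_CLASS_MAX = 7  # 3-7 nt candidates face all four conditions

DEFAULT_MIN_UNIQUE = 2
DEFAULT_MIN_TOTAL = 3
DEFAULT_MIN_FLANK = 8


@dataclass
class MicroexonCandidate:
    interval: GenomicInterval
    unique_junction_reads: int = 0
    total_junction_reads: int = 0
    multi_junction_support: int = 0
    min_flank_len: int | None = None
    annotated: bool = False
    samples: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        n = len(self.interval)
        if not MIN_MICROEXON <= n <= MAX_MICROEXON:
            raise ValueError(f"candidate length {n} outside 3-30 nt")

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def key(self) -> tuple[str, int, int, str]:
        iv = self.interval
        return (iv.contig, iv.start, iv.end, iv.strand)


@dataclass(frozen=True)
class ReliabilityVerdict:
    reliable: bool
    failed_conditions: frozenset[int]

    def __post_init__(self) -> None:
        assert self.reliable == (not self.failed_conditions)


def collect_candidates(
    alignments: list[SplicedAlignment],
    annotation: GeneAnnotation | None = None,
) -> list[MicroexonCandidate]:
    """Aggregate junction evidence into microexon candidates.

    Candidates are keyed by exact (contig, start, end, strand); boundary
    variants are separate candidates. Duplicate reads are not collapsed here;
    instead ``unique_junction_reads`` counts distinct alignment block
    patterns among the supporters.
    """
    # Pass 1: candidate intervals = middle parts of 3..30 nt.
    keys: set[tuple[str, int, int, str]] = set()
    for aln in alignments:
        last = len(aln.blocks) - 1
        for i in range(1, last):
            s, e = aln.blocks[i]
            if MIN_MICROEXON <= e - s <= MAX_MICROEXON:
                keys.add((aln.contig, s, e, aln.strand))
    # Pass 2: count support.
    candidates: dict[tuple, MicroexonCandidate] = {}
    patterns: dict[tuple, set] = {k: set() for k in keys}
    for aln in alignments:
        last = len(aln.blocks) - 1
        if last < 1:
            continue
        for i, (s, e) in enumerate(aln.blocks):
            key = (aln.contig, s, e, aln.strand)
            if key not in patterns:
                continue
            cand = candidates.get(key)
            if cand is None:
                cand = MicroexonCandidate(GenomicInterval(*key))
                candidates[key] = cand
            cand.total_junction_reads += 1
            if aln.sample is not None:
                cand.samples[aln.sample] += 1
            patterns[key].add((aln.strand, aln.blocks))
            if 0 < i < last:
                cand.multi_junction_support += 1
                flank = min(
                    aln.blocks[i - 1][1] - aln.blocks[i - 1][0],
                    aln.blocks[i + 1][1] - aln.blocks[i + 1][0],
                )
                if cand.min_flank_len is None or flank < cand.min_flank_len:
                    cand.min_flank_len = flank
    annotated_exons = annotation.exon_keys() if annotation is not None else set()
    out = []
    for key, cand in candidates.items():
        cand.unique_junction_reads = len(patterns[key])
        cand.annotated = key in annotated_exons
        out.append(cand)
    out.sort(key=lambda c: c.key)
    return out


def assess_reliability(
    candidate: MicroexonCandidate,
    min_unique: int = DEFAULT_MIN_UNIQUE,
    min_total: int = DEFAULT_MIN_TOTAL,
    min_flank: int = DEFAULT_MIN_FLANK,
    short_needs_multi: bool = True,
) -> ReliabilityVerdict:
    """Apply the four-condition filter to one candidate.

    Length 8-30 nt: reliable iff conditions 1 and 2 hold. Length 3-7 nt:
    reliable iff all four hold (condition 4 checks the minimum flanking block
    length across supporting multi-junction reads).
    """
    failed = set()
    if candidate.unique_junction_reads < min_unique:
        failed.add(1)
    if candidate.total_junction_reads < min_total:
        failed.add(2)
    if candidate.length <= SHORT_CLASS_MAX and short_needs_multi:
        if candidate.multi_junction_support < 1:
            failed.add(3)
        if candidate.min_flank_len is None or candidate.min_flank_len < min_flank:
            failed.add(4)
    return ReliabilityVerdict(not failed, frozenset(failed))


def classify_novelty(
    candidate: MicroexonCandidate, annotation: GeneAnnotation
) -> str:
    """'annotated' iff an exon with identical boundaries and strand exists."""
    return "annotated" if candidate.key in annotation.exon_keys() else "novel"


def summarize_lengths(
    candidates: list[MicroexonCandidate],
) -> tuple[dict[int, int], float | None]:
    """Length histogram (3..30) and the fraction with length divisible by 3."""
    hist = {n: 0 for n in range(MIN_MICROEXON, MAX_MICROEXON + 1)}
    for c in candidates:
        hist[c.length] += 1
    total = sum(hist.values())
    if total == 0:
        return {}, None
    frac3n = sum(v for n, v in hist.items() if n % 3 == 0) / total
    return hist, frac3n


def candidates_table(
    candidates: list[MicroexonCandidate],
    annotation: GeneAnnotation | None = None,
    **filter_params,
) -> pd.DataFrame:
    """One row per candidate: coordinates, counts, verdict, novelty, region."""
    rows = []
    for c in candidates:
        verdict = assess_reliability(c, **filter_params)
        row = {
            "contig": c.interval.contig,
            "start": c.interval.start,
            "end": c.interval.end,
            "strand": c.strand,
            "length": c.length,
            "unique_junction_reads": c.unique_junction_reads,
            "total_junction_reads": c.total_junction_reads,
            "multi_junction_support": c.multi_junction_support,
            "min_flank_len": c.min_flank_len,
            "reliable": verdict.reliable,
            "failed_conditions": ",".join(map(str, sorted(verdict.failed_conditions))),
        }
        if annotation is not None:
            row["novelty"] = classify_novelty(c, annotation)
            row["region"] = classify_region(annotation, c.interval)
        rows.append(row)
    return pd.DataFrame(rows)
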