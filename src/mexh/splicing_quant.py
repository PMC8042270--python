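"""PSI quantification of exon-microexon-exon events.

For a trio (upstream exon, cassette, downstream exon) the inclusion isoform
contributes reads over the two inclusion junctions (upstream->cassette and
cassette->downstream) while the skip isoform contributes reads over the
direct upstream->downstream junction. Percent spliced in is

    PSI = I / (I + S),   I = (inclusion_up + inclusion_down) / 2

the averaging correcting the double count of the inclusion isoform's two
junctions (a read may cross both, since a microexon is shorter than a read).
An event is alternatively spliced (AS) when some informative sample has
0 < PSI < 1 (or samples disagree between 0 and 1) and constitutively spliced
(CS) when PSI = 1 in every informative sample. A difference of |dPSI| > 0.05
between two samples is called significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GeneAnnotation, GenomicInterval
from .microexon_caller import MicroexonCandidate
from .read_model import SplicedAlignment

DEFAULT_DELTA_THRESHOLD = 0.05
DEFAULT_PSI_ON = 0.10
DEFAULT_PSI_OFF = 0.05

AS = "AS"
CS = "CS"
UNCLASSIFIED = "unclassified"


@dataclass
class TrioEvent:
    upstream: GenomicInterval
    cassette: GenomicInterval
    downstream: GenomicInterval
    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    # counts[sample] = (inclusion_up, inclusion_down, skip)

    def __post_init__(self) -> None:
        if not (self.upstream.end <= self.cassette.start
                and self.cassette.end <= self.downstream.start):
            raise ValueError("trio intervals must be ordered and non-overlapping")
        if len({self.upstream.strand, self.cassette.strand,
                self.downstream.strand}) != 1:
            raise ValueError("trio intervals must share a strand")

    @property
    def key(self):
        c = self.cassette
        return (c.contig, c.start, c.end, c.strand)


@dataclass(frozen=True)
class PsiRecord:
    event_key: tuple
    sample: str
    psi: float | None
    informative: bool


@dataclass(frozen=True)
class DeltaPsiRecord:
    event_key: tuple
    sample_a: str
    sample_b: str
    delta: float
    significant: bool


def _junction_index(alignments: list[SplicedAlignment]):
    """Per-sample counts of every junction (contig, strand, donor, acceptor)."""
    idx: dict[tuple, dict[str | None, int]] = {}
    for aln in alignments:
        for key in aln.junction_keys():
            per = idx.setdefault(key, {})
            per[aln.sample] = per.get(aln.sample, 0) + 1
    return idx


def detect_trios(
    candidates: list[MicroexonCandidate],
    alignments: list[SplicedAlignment],
    annotation: GeneAnnotation | None = None,
    samples: list[str] | None = None,
) -> list[TrioEvent]:
    """Build exon-cassette-exon events for candidates with flanks on both sides.

    Flanking exon boundaries come from observed junction evidence; the flank
    interval itself is the matching annotated exon when one exists, otherwise
    the junction-adjacent aligned block. Candidates lacking an upstream or a
    downstream junction partner (e.g. first/last exons) yield no trio.
    """
    jidx = _junction_index(alignments)
    if samples is None:
        samples = sorted(
            {a.sample for a in alignments if a.sample is not None}
        ) or [None]
    ann_exons = []
    if annotation is not None:
        for g in annotation.genes:
            for t in g.transcripts:
                ann_exons.extend(t.exons)
    events = []
    for cand in candidates:
        iv = cand.interval
        ups = sorted({
            k[2] for k in jidx
            if k[0] == iv.contig and k[1] == iv.strand and k[3] == iv.start
        })
        downs = sorted({
            k[3] for k in jidx
            if k[0] == iv.contig and k[1] == iv.strand and k[2] == iv.end
        })
        if not ups or not downs:
            continue
        # Pair each candidate with its nearest flanks.
        u_end = max(ups)
        d_start = min(downs)
        upstream = _flank_interval(ann_exons, alignments, iv, u_end, left=True)
        downstream = _flank_interval(ann_exons, alignments, iv, d_start, left=False)
        event = TrioEvent(upstream, iv, downstream)
        for sample in samples:
            inc_up = jidx.get((iv.contig, iv.strand, u_end, iv.start), {}).get(sample, 0)
            inc_dn = jidx.get((iv.contig, iv.strand, iv.end, d_start), {}).get(sample, 0)
            skip = jidx.get((iv.contig, iv.strand, u_end, d_start), {}).get(sample, 0)
            event.counts[sample] = (inc_up, inc_dn, skip)
        events.append(event)
    return events


def _flank_interval(ann_exons, alignments, cassette, boundary, left):
    for e in ann_exons:
        if e.contig != cassette.contig or e.strand != cassette.strand:
            continue
        if left and e.end == boundary:
            return e
        if not left and e.start == boundary:
            return e
    # Fall back to the widest junction-adjacent aligned block.
    best = None
    for aln in alignments:
        if aln.contig != cassette.contig or aln.strand != cassette.strand:
            continue
        for s, e in aln.blocks:
            if left and e == boundary:
                best = min(best, s) if best is not None else s
            if not left and s == boundary:
                best = max(best, e) if best is not None else e
    if left:
        start = best if best is not None else boundary - 1
        return GenomicInterval(cassette.contig, start, boundary, cassette.strand)
    end = best if best is not None else boundary + 1
    return GenomicInterval(cassette.contig, boundary, end, cassette.strand)


def compute_psi(event: TrioEvent, sample: str) -> PsiRecord:
    inc_up, inc_dn, skip = event.counts.get(sample, (0, 0, 0))
    inclusion = (inc_up + inc_dn) / 2.0
    denom = inclusion + skip
    if denom <= 0:
        return PsiRecord(event.key, sample, None, False)
    return PsiRecord(event.key, sample, inclusion / denom, True)


def classify_as_cs(event: TrioEvent, psi_records: list[PsiRecord]) -> str:
    """AS iff any informative PSI is strictly between 0 and 1, or informative
    samples disagree between 0 and 1; CS iff PSI = 1 everywhere informative."""
    psis = [r.psi for r in psi_records if r.informative]
    if not psis:
        return UNCLASSIFIED
    if any(0.0 < p < 1.0 for p in psis):
        return AS
    if len({p for p in psis}) > 1:  # {0, 1} disagreement
        return AS
    if psis[0] == 1.0:
        return CS
    return UNCLASSIFIED  # inclusion never observed: excluded from the census


def delta_psi(
    event: TrioEvent,
    sample_a: str,
    sample_b: str,
    threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> DeltaPsiRecord:
    ra = compute_psi(event, sample_a)
    rb = compute_psi(event, sample_b)
    if not (ra.informative and rb.informative):
        raise ValueError(
            f"uninformative sample for event {event.key}: "
            f"{sample_a if not ra.informative else sample_b}"
        )
    delta = ra.psi - rb.psi
    # Round the excess to 9 decimals so that |delta| equal to the threshold
    # up to float representation noise is never called significant.
    significant = round(abs(delta) - threshold, 9) > 0
    return DeltaPsiRecord(event.key, sample_a, sample_b, delta, significant)


def tissue_specific(
    events: list[TrioEvent],
    sample_groups: dict[str, list[str]],
    psi_on: float = DEFAULT_PSI_ON,
    psi_off: float = DEFAULT_PSI_OFF,
) -> list[tuple[TrioEvent, str]]:
    """Events included in every sample of one group and skipped elsewhere.

    An event is specific to group G iff PSI >= psi_on in every sample of G
    and PSI <= psi_off in every *informative* sample of all other groups.
    """
    if len(sample_groups) < 2:
        return []
    out = []
    for event in events:
        for group, members in sample_groups.items():
            records = [compute_psi(event, s) for s in members]
            if not records or not all(r.informative for r in records):
                continue
            if not all(r.psi >= psi_on for r in records):
                continue
            others = [
                compute_psi(event, s)
                for g, mem in sample_groups.items() if g != group
                for s in mem
            ]
            informative_others = [r for r in others if r.informative]
            if not informative_others:
                continue
            if all(r.psi <= psi_off for r in informative_others):
                out.append((event, group))
                break
    return out


def long_exon_comparison(
    annotation: GeneAnnotation,
    alignments: list[SplicedAlignment],
    min_length: int = 31,
    samples: list[str] | None = None,
) -> dict:
    """Run the trio/PSI/AS-CS machinery on annotated internal exons > 30 nt."""
    jidx = _junction_index(alignments)
    if samples is None:
        samples = sorted(
            {a.sample for a in alignments if a.sample is not None}
        ) or [None]
    n_as = n_cs = 0
    events = []
    seen = set()
    for gene, tx, i in annotation.internal_exons(min_length=min_length):
        up, mid, down = tx.exons[i - 1], tx.exons[i], tx.exons[i + 1]
        if mid.start - up.end < 20 or down.start - mid.end < 20:
            continue
        if (mid.contig, mid.start, mid.end, mid.strand) in seen:
            continue
        seen.add((mid.contig, mid.start, mid.end, mid.strand))
        event = TrioEvent(up, mid, down)
        for sample in samples:
            inc_up = jidx.get((mid.contig, mid.strand, up.end, mid.start), {}).get(sample, 0)
            inc_dn = jidx.get((mid.contig, mid.strand, mid.end, down.start), {}).get(sample, 0)
            skip = jidx.get((mid.contig, mid.strand, up.end, down.start), {}).get(sample, 0)
            event.counts[sample] = (inc_up, inc_dn, skip)
        label = classify_as_cs(
            event, [compute_psi(event, s) for s in samples]
        )
        events.append((event, label))
        if label == AS:
            n_as += 1
        elif label == CS:
            n_cs += 1
    classified = n_as + n_cs
    return {
        "events": events,
        "n_as": n_as,
        "n_cs": n_cs,
        "as_fraction": (n_as / classified) if classified else None,
    }


def psi_table(events: list[TrioEvent], samples: list[str]) -> pd.DataFrame:
    rows = []
    for event in events:
        for sample in samples:
            rec = compute_psi(event, sample)
            inc_up, inc_dn, skip = event.counts.get(sample, (0, 0, 0))
            rows.append({
                "contig": event.cassette.contig,
                "start": event.cassette.start,
                "end": event.cassette.end,
                "strand": event.cassette.strand,
                "sample": sample,
                "inclusion_up": inc_up,
                "inclusion_down": inc_dn,
                "skip": skip,
                "psi": rec.psi,
                "informative": rec.informative,
            })
    return pd.DataFrame(rows)
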