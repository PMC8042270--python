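"""Wiring between the stages: remap -> call -> quantify."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cutend_remapper import DEFAULT_MAX_CYCLES, CutEndRemapper
from .genome_io import GeneAnnotation, Genome
from .microexon_caller import (
    MicroexonCandidate,
    assess_reliability,
    candidates_table,
    collect_candidates,
)
from .read_model import SplicedAlignment, UnmappedRead, collect_junction_keys


@dataclass
class DiscoveryResult:
    recovered: list[SplicedAlignment]
    cycle_stats: list[int]
    candidates: list[MicroexonCandidate]
    reliable: list[MicroexonCandidate]
    table: pd.DataFrame


def run_discovery(
    genome: Genome,
    annotation: GeneAnnotation,
    alignments: list[SplicedAlignment],
    unmapped: list[UnmappedRead],
    max_cycles: int = DEFAULT_MAX_CYCLES,
    remapper_params: dict | None = None,
    filter_params: dict | None = None,
) -> DiscoveryResult:
    """Recover unmapped reads, then call and filter microexon candidates.

    Junctions already present in the primary alignments seed the remapper's
    known-junction set (the reconstructed transcriptome).
    """
    remapper = CutEndRemapper(
        genome, annotation,
        extra_junctions=collect_junction_keys(alignments),
        **(remapper_params or {}),
    )
    recovered, stats = remapper.run_cycles(unmapped, max_cycles=max_cycles)
    all_alignments = list(alignments) + recovered
    candidates = collect_candidates(all_alignments, annotation)
    fp = filter_params or {}
    reliable = [c for c in candidates if assess_reliability(c, **fp).reliable]
    table = candidates_table(candidates, annotation, **fp)
    return DiscoveryResult(recovered, stats, candidates, reliable, table)


def alignments_to_frame(alignments: list[SplicedAlignment]) -> pd.DataFrame:
    rows = []
    for a in alignments:
        rows.append({
            "read_id": a.read_id,
            "contig": a.contig,
            "strand": a.strand,
            "blocks": ",".join(f"{s}-{e}" for s, e in a.blocks),
            "mismatches": a.mismatches,
            "source": a.source,
            "sample": a.sample or "",
        })
    return pd.DataFrame(rows)


def alignments_from_frame(frame: pd.DataFrame) -> list[SplicedAlignment]:
    out = []
    for row in frame.itertuples(index=False):
        blocks = tuple(
            tuple(int(x) for x in part.split("-")) for part in row.blocks.split(",")
        )
        out.append(
            SplicedAlignment(
                row.read_id, row.contig, row.strand, blocks,
                mismatches=int(row.mismatches), source=row.source,
                sample=row.sample or None,
            )
        )
    return out
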