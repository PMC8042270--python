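"""Splice-site window extraction and strength scoring.

Window conventions: a donor (5'SS) window is 9 nt — the last 3 exonic plus
the first 6 intronic nucleotides; an acceptor (3'SS) window is 23 nt — the
last 20 intronic plus the first 3 exonic nucleotides, both read on the
transcribed strand.

Two scoring models are exposed. The default is a position weight matrix
trained on the splice sites of a supplied annotation (log2 odds against a
uniform background, pseudocount 0.5 per base per column). A table-driven
maximum-entropy scorer can be plugged in instead by pointing it at parameter
tables in the layout documented on :class:`MaxEntTablesModel`; those tables
are an external input and are never bundled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import Genome, GeneAnnotation, GenomicInterval

DONOR = "donor_9mer"
ACCEPTOR = "acceptor_23mer"
WINDOW_LENGTH = {DONOR: 9, ACCEPTOR: 23}
_DONOR_EXONIC, _DONOR_INTRONIC = 3, 6
_ACCEPTOR_INTRONIC, _ACCEPTOR_EXONIC = 20, 3
_BASES = "ACGT"


@dataclass(frozen=True)
class SpliceSiteWindow:
    kind: str
    sequence: str
    owner: str = ""

    def __post_init__(self) -> None:
        if self.kind not in WINDOW_LENGTH:
            raise ValueError(f"unknown window kind {self.kind!r}")
        if len(self.sequence) != WINDOW_LENGTH[self.kind]:
            raise ValueError(
                f"{self.kind} window must be {WINDOW_LENGTH[self.kind]} nt, "
                f"got {len(self.sequence)}"
            )


def donor_window(genome: Genome, exon: GenomicInterval, owner: str = "") -> SpliceSiteWindow:
    """The 5'SS window at the transcript-3' boundary of *exon*."""
    if len(exon) < _DONOR_EXONIC:
        raise ValueError(f"donor at {exon}: exonic side shorter than 3 nt")
    if exon.strand == "+":
        iv = GenomicInterval(exon.contig, exon.end - 3, exon.end + 6, "+")
    else:
        iv = GenomicInterval(exon.contig, exon.start - 6, exon.start + 3, "-")
    try:
        seq = genome.fetch(iv)
    except ValueError as err:
        raise ValueError(f"donor window at {exon}: {err}") from None
    return SpliceSiteWindow(DONOR, seq, owner)


def acceptor_window(genome: Genome, exon: GenomicInterval, owner: str = "") -> SpliceSiteWindow:
    """The 3'SS window at the transcript-5' boundary of *exon*."""
    if len(exon) < _ACCEPTOR_EXONIC:
        raise ValueError(f"acceptor at {exon}: exonic side shorter than 3 nt")
    if exon.strand == "+":
        iv = GenomicInterval(exon.contig, exon.start - 20, exon.start + 3, "+")
    else:
        iv = GenomicInterval(exon.contig, exon.end - 3, exon.end + 20, "-")
    try:
        seq = genome.fetch(iv)
    except ValueError as err:
        raise ValueError(f"acceptor window at {exon}: {err}") from None
    return SpliceSiteWindow(ACCEPTOR, seq, owner)


def extract_windows(genome: Genome, trio) -> dict[str, SpliceSiteWindow]:
    """All six windows of an exon-microexon-exon trio, keyed by owner."""
    return {
        "upstream_5ss": donor_window(genome, trio.upstream, "upstream_5ss"),
        "cassette_3ss": acceptor_window(genome, trio.cassette, "cassette_3ss"),
        "cassette_5ss": donor_window(genome, trio.cassette, "cassette_5ss"),
        "downstream_3ss": acceptor_window(genome, trio.downstream, "downstream_3ss"),
    }


def position_frequency_matrix(windows: list[SpliceSiteWindow]) -> pd.DataFrame:
    """Per-position base frequencies (rows A/C/G/T, columns sum to 1).

    N bases are excluded from column denominators.
    """
    if not windows:
        raise ValueError("no windows supplied")
    kinds = {w.kind for w in windows}
    if len(kinds) != 1:
        raise ValueError(f"mixed window kinds: {sorted(kinds)}")
    length = WINDOW_LENGTH[windows[0].kind]
    counts = np.zeros((4, length))
    for w in windows:
        for j, base in enumerate(w.sequence):
            i = _BASES.find(base)
            if i >= 0:
                counts[i, j] += 1
    denom = counts.sum(axis=0)
    denom[denom == 0] = 1.0
    return pd.DataFrame(counts / denom, index=list(_BASES),
                        columns=range(length))


class PwmSpliceModel:
    """Log-odds PWM splice model: score = sum_j log2(f_j(base) / 0.25)."""

    def __init__(self, kind: str, logodds: np.ndarray):
        if logodds.shape != (4, WINDOW_LENGTH[kind]):
            raise ValueError("log-odds matrix shape mismatch")
        self.kind = kind
        self.logodds = logodds

    @classmethod
    def uniform(cls, kind: str) -> "PwmSpliceModel":
        return cls(kind, np.zeros((4, WINDOW_LENGTH[kind])))

    @classmethod
    def from_windows(
        cls, windows: list[SpliceSiteWindow], pseudocount: float = 0.5
    ) -> "PwmSpliceModel":
        kind = windows[0].kind
        length = WINDOW_LENGTH[kind]
        counts = np.full((4, length), pseudocount)
        for w in windows:
            if w.kind != kind:
                raise ValueError("mixed window kinds")
            for j, base in enumerate(w.sequence):
                i = _BASES.find(base)
                if i >= 0:
                    counts[i, j] += 1
        freqs = counts / counts.sum(axis=0, keepdims=True)
        return cls(kind, np.log2(freqs / 0.25))

    @classmethod
    def train_from_annotation(
        cls, genome: Genome, annotation: GeneAnnotation, kind: str,
        pseudocount: float = 0.5,
    ) -> "PwmSpliceModel":
        """Train on every annotated internal splice site of the right kind."""
        windows = []
        for gene in annotation.genes:
            for tx in gene.transcripts:
                exons = tx.exons if tx.strand == "+" else tx.exons[::-1]
                for i, exon in enumerate(exons):
                    try:
                        if kind == DONOR and i < len(exons) - 1:
                            windows.append(donor_window(genome, exon))
                        elif kind == ACCEPTOR and i > 0:
                            windows.append(acceptor_window(genome, exon))
                    except ValueError:
                        continue  # insufficient flanking sequence at the edge
        if not windows:
            raise ValueError(f"annotation provides no {kind} training windows")
        return cls.from_windows(windows, pseudocount)

    def score(self, window: SpliceSiteWindow) -> float:
        if window.kind != self.kind:
            raise ValueError(
                f"window kind {window.kind} does not match model {self.kind}"
            )
        total = 0.0
        for j, base in enumerate(window.sequence):
            i = _BASES.find(base)
            total += self.logodds[i, j] if i >= 0 else 0.0
        return float(total)


class MaxEntTablesModel:
    """Maximum-entropy splice scorer driven by external parameter tables.

    Expected layout under ``table_dir``:

    * donor: ``me2x5`` — 16384 lines, one probability per enumerated 7-mer
      over the non-consensus positions (0,1,2,5,6,7,8) of the 9-mer window in
      lexicographic A<C<G<T order — and ``cons5`` with lines
      ``<pos> <base> <prob>`` giving consensus-position (3 and 4, the GT)
      probabilities.
    * acceptor: ``acc23.tsv`` — two tab-separated columns, 23-mer and score.

    Scores are log2 odds against a uniform background, matching the published
    scorer's scale when fed its distribution tables.
    """

    def __init__(self, kind: str, table_dir):
        self.kind = kind
        d = Path(table_dir)
        if kind == DONOR:
            me2x5 = d / "me2x5"
            cons5 = d / "cons5"
            if not me2x5.exists() or not cons5.exists():
                raise FileNotFoundError(
                    f"maxent donor tables not found under {d}; supply 'me2x5' "
                    "and 'cons5' or fall back to the annotation-trained PWM "
                    "(PwmSpliceModel.train_from_annotation)"
                )
            self._probs = [float(x) for x in me2x5.read_text().split()]
            if len(self._probs) != 4 ** 7:
                raise ValueError("me2x5 must list 4^7 probabilities")
            self._cons = {}
            for line in cons5.read_text().splitlines():
                pos, base, prob = line.split()
                self._cons[(int(pos), base)] = float(prob)
        elif kind == ACCEPTOR:
            table = d / "acc23.tsv"
            if not table.exists():
                raise FileNotFoundError(
                    f"maxent acceptor table not found under {d}; supply "
                    "'acc23.tsv' or fall back to the annotation-trained PWM"
                )
            self._lookup = {}
            for line in table.read_text().splitlines():
                kmer, score = line.split("\t")
                self._lookup[kmer] = float(score)
        else:
            raise ValueError(f"unknown window kind {kind!r}")

    def score(self, window: SpliceSiteWindow) -> float:
        if window.kind != self.kind:
            raise ValueError(
                f"window kind {window.kind} does not match model {self.kind}"
            )
        seq = window.sequence
        if self.kind == ACCEPTOR:
            try:
                return self._lookup[seq]
            except KeyError:
                raise ValueError(f"23-mer {seq} absent from acceptor table") from None
        free = [seq[i] for i in (0, 1, 2, 5, 6, 7, 8)]
        idx = 0
        for base in free:
            idx = idx * 4 + _BASES.index(base)
        p = self._probs[idx]
        c1 = self._cons.get((1, seq[3]), 0.25)
        c2 = self._cons.get((2, seq[4]), 0.25)
        return math.log2((c1 / 0.25) * (c2 / 0.25) * (p / 0.25 ** 7))


def score_splice_site(model, window: SpliceSiteWindow) -> float:
    return model.score(window)


def compare_strength(
    scores_a: list[float], scores_b: list[float]
) -> dict[str, float]:
    """Rank-sum comparison of two splice-site score sets (two-sided)."""
    u, p = stats.mannwhitneyu(scores_a, scores_b, alternative="two-sided")
    return {
        "u_statistic": float(u),
        "p_value": float(p),
        "median_a": float(np.median(scores_a)),
        "median_b": float(np.median(scores_b)),
        "n_a": len(scores_a),
        "n_b": len(scores_b),
    }
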