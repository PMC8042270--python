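# Methods

This note records the model behind `mexh`, the parameter choices that
matter, the design decisions taken where the procedure was genuinely open,
and what the simulator-based tests do and do not demonstrate.

## Recovery model

A spliced aligner that requires an anchor of ~8 nt on each side of a
junction cannot place a read whose alignment needs a 3–7 nt exonic segment,
whether that segment sits at the read's end (a terminal overhang into a
microexon) or in its middle (a fully contained microexon flanked by two
junctions). `mexh` treats those two situations separately.

*Middle segments* are handled by the spliced placer directly: a middle
block of 3–7 nt is admitted de novo provided both of its introns carry the
canonical GT..AG motif on the transcribed strand and lie within the gap
bounds, because the block is pinned by ≥ 8 nt anchored blocks on both
sides. Blocks shorter than 3 nt are never admitted de novo — 3 nt is the
lower bound of the microexon definition, and 1–2 nt patterns match too
promiscuously to carry evidence.

*Terminal segments* cannot be pinned this way, which is exactly the
motivation for cut-end recovery: the segment is removed, the trunk is
placed under the strict contract (0 mismatches, terminal anchors ≥ 8 nt),
and the segment becomes a constrained search problem — exact match,
`AG/segment/GT` transcribed-strand context, gap of 20–10,000 nt, inside the
host gene span, uniquely placeable in that window. We additionally require
the trunk-adjacent end of the bridging intron to carry its canonical
dinucleotide; without this the package could emit recovered alignments
whose introns are not GT..AG, violating the invariant that every junction
it reports is canonical.

### Placement rules in full

A placement assigns the query to genome blocks with zero mismatches. For
each junction between consecutive blocks, either

* the junction is **known** — annotated in the GTF, observed in the primary
  alignments (the reconstructed transcriptome), or discovered in an earlier
  recovery cycle; known junctions are exempt from the de novo gap bounds —
  or
* the junction is **de novo**: canonical GT..AG (CT..AC on the forward
  strand of minus genes) with a gap in [20, 10,000] nt.

Terminal blocks must reach the anchor length (8 nt) unless they rest on a
known junction, in which case any length ≥ 1 nt is accepted (the junction
fixes their position exactly). Middle blocks follow the 3 nt rule above.
Both match orientations of the query are searched, and junction motifs are
validated against either transcribed strand — sequencing orientation does
not determine transcript strand.

**Uniqueness and tie-breaking.** Among all placements of a read (or
trunk), the class with the fewest junctions is preferred — the parsimony
order every production aligner uses — and the read is kept only when that
class contains exactly one placement. This stops a chance many-junction
chimera (observed in simulation: a 4-block chimeric match assembled from
chance motifs) from vetoing the parsimonious placement, while genuine
ambiguity still discards the read. When several (side, k) derivatives of
one read reconstruct successfully, they are kept only if they agree on the
final alignment; conflicting reconstructions discard the read, since
ambiguity must not fabricate support.

**Cycles.** Each cycle attempts direct placement first (it subsumes the
middle-segment group), then the cut-end path. Junctions of newly recovered
alignments join the known set, so a read whose trunk needs a junction that
only another read can reveal is recovered one cycle later. In simulations
at 30× coverage recovery converges in ≤ 3 cycles; the default
`max_cycles = 3` reflects that.

## Candidate calling and the reliability filter

Candidates are keyed by exact (contig, start, end, strand); a read supports
a candidate iff one of its aligned blocks equals the candidate interval.
Middle parts create candidates and count as multi-junction support; end
parts (reads terminating exactly at the exon boundary) add support only
when the interval is independently seen as a middle part — the conservative
reading of extending single-junction end evidence by other reads. "Unique"
support counts distinct alignment block patterns, the standard guard
against PCR duplicates.

The filter applies conditions (1) unique ≥ 2, (2) total ≥ 3 to 8–30 nt
candidates and all four conditions to 3–7 nt candidates, with condition (4)
evaluated as the *minimum* flanking block length across all supporting
multi-junction reads (an alternative per-best-read reading exists; the
minimum is the stricter choice and is applied consistently in the truth
accounting). A practical consequence, reproduced in simulation: one
recovered supporter with a short (< 8 nt) flank disqualifies a 3–7 nt
candidate, so reliable 3–7 nt microexons are considerably rarer than
8–30 nt ones at equal coverage.

## PSI machinery

The junction-count estimator `PSI = ((u + d)/2) / ((u + d)/2 + s)` averages
the two inclusion junctions because a read shorter than the flanking exons
but longer than the microexon typically crosses both, double-counting the
inclusion isoform relative to the single skip junction. Reads that end
inside the microexon cross only one inclusion junction, which biases the
estimate slightly downward at low coverage; the event-level calibration
(200 events, ≥ 40 junction fragments) shows the estimator within
3·sqrt(π(1−π)/n) of the designed level for ≥ 99% of events when inclusion
reads span both junctions.

Events with PSI = 0 everywhere informative are excluded from the AS/CS
census (a microexon called from junction evidence cannot be included
nowhere); cross-sample {0, 1} disagreement is AS. The ΔPSI significance
test compares |Δ| to 0.05 after rounding the excess to 9 decimals, so a
difference equal to the threshold up to float representation noise is never
called significant. Tissue-specific calls use PSI ≥ 0.10 in every sample of
one group and ≤ 0.05 in every informative sample of the others — config
knobs aligned with the ΔPSI scale, since no sharper rule is established.

## Splice-site scoring

Donor windows are 9-mers (last 3 exonic + first 6 intronic nt), acceptor
windows 23-mers (last 20 intronic + first 3 exonic nt), on the transcribed
strand. The default model is a log-odds PWM trained on the supplied
annotation's splice sites with a pseudocount of 0.5 per base per column
(avoiding −∞ on small training sets), scored against a uniform background.
A maximum-entropy table model can be substituted; its parameter tables are
an external input with a documented layout and are never bundled, so the
PWM is the no-download default and the missing-table error names the
fallback.

## Simulator

The simulator emulates the study conditions: multi-exon genes (4–6 exons of
80–300 nt, introns 50–2,000 nt) on a random genome, paired-end 100 or
150 nt reads (fr-firststrand or unstranded), fragment length N(250, 30),
30× default coverage, substitution error rate 0 by default (the method's
contracts are exact-match; an error mode exists to exercise the rejection
path). Planted microexons get canonical GT..AG introns, an
`AG/segment/GT` context verified unique within the host gene, and flanking
exons at least one read long so a read spanning the microexon cannot reach
a second gene junction. A configurable fraction (default 0.4) is withheld
from the GTF to test novelty calling. The mask policy declares a read
unmapped iff its true alignment contains a block ≤ 7 nt — the failure mode
of the primary aligner — rather than running a real mapper, which keeps the
test bed deterministic and isolates this package's algorithmics.

The truth table's expected support counts mirror the recovery contract
applied to each read's true placement (masked iff any block ≤ 7 nt;
recoverable once every short terminal block rests on a known junction; the
cut-end path first publishes a microexon junction when a read's single
offending terminal block coincides with the full microexon). Pipeline and
truth agree exactly on support counts and verdicts across seeds; per-cycle
totals can differ by a read or two where chance flanking motifs open an
extra recovery path the idealized accounting ignores.

**What passing tests do not show.** The simulator draws genome sequence
uniformly at random: it has no repeats beyond chance, no paralogy, no
expression-level or GC realism, no indels or quality-dependent errors, and
its splice sites are motif-exact. Results on real data will be degraded by
repetitive context (more non-unique placements), sequencing error (the
exact-match contract discards affected reads), and non-canonical introns
(out of scope by design).

## Problem sizes

Test and acceptance runs use desk-scale problems chosen to exercise every
code path while keeping the suite quick: 10-gene/6-microexon fixtures for
unit tests, the 50-gene/25-microexon/30× dataset (~14k reads, ~300 kb
genome, ~1.1k masked reads) for end-to-end recovery, 20 random ≤ 50 kb
genomes × 200 segments for the exhaustive-scan equivalence check, and a
10,201-cell lattice for ΔPSI significance.
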