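import numpy as np
import pytest
from hypothesis import given, strategies as st

from helpers import brute_force_segment_scan, microexon_gene, rand_seq
from mexh.cutend_remapper import (
    FIVE_PRIME,
    THREE_PRIME,
    CutEndRead,
    CutEndRemapper,
    TrunkPlacement,
    generate_derivatives,
)
from mexh.genome_io import (
    Gene,
    GeneAnnotation,
    Genome,
    GenomicInterval,
    Transcript,
    reverse_complement,
)
from mexh.read_model import UnmappedRead


class TestDerivatives:
    def test_long_read_yields_all_ten(self):
        seq = rand_seq(np.random.default_rng(0), 100)
        derivatives = generate_derivatives(seq, "r")
        assert len(derivatives) == 10
        assert {(d.side, d.k) for d in derivatives} == {
            (side, k) for side in (FIVE_PRIME, THREE_PRIME) for k in range(3, 8)
        }

    def test_cut_arithmetic(self):
        seq = rand_seq(np.random.default_rng(1), 100)
        (d,) = [
            d for d in generate_derivatives(seq, "r")
            if d.side == FIVE_PRIME and d.k == 4
        ]
        assert len(d.trunk) == 96
        assert d.segment == seq[:4]
        assert d.segment + d.trunk == seq

    def test_short_read_yields_none(self):
        # 18 nt: every trunk would be <= 15 nt, below the 16 nt minimum.
        assert generate_derivatives("A" * 18, "r") == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            generate_derivatives("", "r")

    @given(st.integers(min_value=1, max_value=60))
    def test_derivative_count_matches_enumeration(self, length):
        seq = "A" * length
        expected = sum(2 for k in range(3, 8) if length - k >= 16)
        derivatives = generate_derivatives(seq, "r")
        assert len(derivatives) == min(expected, 10)
        assert (len(derivatives) == 10) == (length >= 23)
        for d in derivatives:
            parent = (
                d.segment + d.trunk if d.side == FIVE_PRIME else d.trunk + d.segment
            )
            assert parent == seq


@pytest.fixture(scope="module")
def toy_locus():
    genome, annotation, layout = microexon_gene(seed=3)
    return genome, annotation, layout, CutEndRemapper(genome, annotation)


class TestTrunkPlacement:
    def test_verbatim_copy_places_contiguously(self, toy_locus):
        genome, _, layout, rm = toy_locus
        trunk = genome.contigs["c1"][layout["a_start"] : layout["a_start"] + 40]
        placements = rm.remap_trunk(trunk)
        assert [p.blocks for p in placements] == [
            ((layout["a_start"], layout["a_start"] + 40),)
        ]

    def test_spliced_trunk_across_planted_intron(self):
        # Trunk spanning a 500 nt GT..AG intron with 50 nt anchors.
        rng = np.random.default_rng(5)
        left = rand_seq(rng, 300)
        right = rand_seq(rng, 300)
        intron = "GT" + rand_seq(rng, 496) + "AG"
        genome = Genome({"c1": left + intron + right})
        gene = Gene(
            "g", GenomicInterval("c1", 0, 1100, "+"), "protein_coding",
            (Transcript("t", (GenomicInterval("c1", 0, 300, "+"),
                              GenomicInterval("c1", 800, 1100, "+"))),),
        )
        rm = CutEndRemapper(genome, GeneAnnotation((gene,)))
        trunk = left[-50:] + right[:50]
        placements = rm.remap_trunk(trunk)
        assert [p.blocks for p in placements] == [((250, 300), (800, 850))]
        # Brute-force cross-check: the two halves really are where we think.
        cs = genome.contigs["c1"]
        assert cs.count(trunk[:50]) == 1 and cs.index(trunk[:50]) == 250
        assert cs.count(trunk[50:]) == 1 and cs.index(trunk[50:]) == 800

    def test_single_mismatch_rejected(self, toy_locus):
        genome, _, layout, rm = toy_locus
        trunk = genome.contigs["c1"][layout["a_start"] : layout["a_start"] + 40]
        mutated = trunk[:20] + ("A" if trunk[20] != "A" else "C") + trunk[21:]
        assert rm.remap_trunk(mutated) == []

    def test_reverse_complement_read_places_with_minus_orientation(self, toy_locus):
        genome, _, layout, rm = toy_locus
        trunk = genome.contigs["c1"][layout["a_start"] : layout["a_start"] + 40]
        placements = rm.remap_trunk(reverse_complement(trunk))
        assert len(placements) == 1
        assert placements[0].orient == "-"
        assert placements[0].blocks == ((layout["a_start"], layout["a_start"] + 40),)


class TestSegmentPlacement:
    def test_planted_unique_segment(self, toy_locus):
        genome, _, layout, rm = toy_locus
        cs = genome.contigs["c1"]
        me = layout["me_seq"]
        read_seq = cs[layout["a_end"] - 55 : layout["a_end"]] + me
        (d,) = [
            d for d in generate_derivatives(read_seq, "rA")
            if d.side == THREE_PRIME and d.k == len(me)
        ]
        (tp,) = rm.remap_trunk(d.trunk)
        tp = TrunkPlacement(d, tp.contig, tp.strand, tp.blocks, tp.orient)
        placements = rm.place_cut_segment(tp, d)
        assert len(placements) == 1
        seg = placements[0]
        assert seg.unique
        assert (seg.interval.start, seg.interval.end) == (
            layout["me_start"], layout["me_end"],
        )
        assert seg.gap == layout["me_start"] - layout["a_end"]

    def test_duplicated_context_is_not_unique(self):
        genome, annotation, layout = microexon_gene(seed=11)
        cs = genome.contigs["c1"]
        me = layout["me_seq"]
        # Plant a second AG/segment/GT context inside the downstream intron.
        insert_at = layout["me_end"] + 20
        pattern = "AG" + me + "GT"
        cs2 = cs[:insert_at] + pattern + cs[insert_at + len(pattern):]
        genome2 = Genome({"c1": cs2})
        rm = CutEndRemapper(genome2, annotation)
        read_seq = cs2[layout["a_end"] - 55 : layout["a_end"]] + me
        (d,) = [
            d for d in generate_derivatives(read_seq, "rA")
            if d.side == THREE_PRIME and d.k == len(me)
        ]
        (tp,) = rm.remap_trunk(d.trunk)
        tp = TrunkPlacement(d, tp.contig, tp.strand, tp.blocks, tp.orient)
        placements = rm.place_cut_segment(tp, d)
        assert len(placements) == 2
        assert not any(p.unique for p in placements)

    def test_gap_below_minimum_rejected(self):
        genome, annotation, layout = microexon_gene(seed=7, intron_len=60)
        rm = CutEndRemapper(genome, annotation, min_gap=20)
        cs = genome.contigs["c1"]
        me = layout["me_seq"]
        # Shrink the upstream intron to 15 nt by editing the genome.
        i1_start, i1_end = layout["a_end"], layout["me_start"]
        new_i1 = "GT" + cs[i1_start + 2 : i1_start + 13] + "AG"
        cs2 = cs[:i1_start] + new_i1 + cs[i1_end:]
        shift = len(new_i1) - (i1_end - i1_start)
        genome2 = Genome({"c1": cs2})
        gene = annotation.genes[0]
        rm2 = CutEndRemapper(
            genome2,
            GeneAnnotation((Gene(
                gene.gene_id,
                GenomicInterval("c1", gene.span.start, gene.span.end + shift, "+"),
                gene.biotype,
                (Transcript("t", (
                    GenomicInterval("c1", layout["a_start"], layout["a_end"], "+"),
                    GenomicInterval("c1", layout["b_start"] + shift,
                                    layout["b_end"] + shift, "+"),
                )),),
            ),)),
        )
        read_seq = cs2[layout["a_end"] - 55 : layout["a_end"]] + me
        (d,) = [
            d for d in generate_derivatives(read_seq, "rA")
            if d.side == THREE_PRIME and d.k == len(me)
        ]
        trunk_pl = rm2.remap_trunk(d.trunk)
        assert len(trunk_pl) == 1
        tp = TrunkPlacement(d, trunk_pl[0].contig, trunk_pl[0].strand,
                            trunk_pl[0].blocks, trunk_pl[0].orient)
        assert rm2.place_cut_segment(tp, d) == []

    def test_mismatched_segment_copy_rejected(self):
        # A substitution in the genomic copy of the segment kills placement.
        genome, annotation, layout = microexon_gene(seed=13)
        cs = genome.contigs["c1"]
        me = layout["me_seq"]
        p = layout["me_start"]
        mutated = cs[:p] + ("A" if cs[p] != "A" else "C") + cs[p + 1:]
        rm = CutEndRemapper(Genome({"c1": mutated}), annotation)
        read_seq = cs[layout["a_end"] - 55 : layout["a_end"]] + me
        (d,) = [
            d for d in generate_derivatives(read_seq, "rA")
            if d.side == THREE_PRIME and d.k == len(me)
        ]
        (tp,) = rm.remap_trunk(d.trunk)
        tp = TrunkPlacement(d, tp.contig, tp.strand, tp.blocks, tp.orient)
        assert rm.place_cut_segment(tp, d) == []

    def test_trunk_outside_any_gene_skipped(self, toy_locus):
        genome, _, layout, _ = toy_locus
        rm = CutEndRemapper(genome, GeneAnnotation(()))
        d = CutEndRead("r", THREE_PRIME, 5, "A" * 20, "ACGTA")
        tp = TrunkPlacement(d, "c1", "+", ((layout["a_start"], layout["a_end"]),), "+")
        assert rm.place_cut_segment(tp, d) == []
        assert rm.skipped_outside_gene == 1

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(17)
        for trial in range(6):
            genome, annotation, layout = microexon_gene(seed=100 + trial)
            rm = CutEndRemapper(genome, annotation)
            gene = annotation.genes[0]
            me = layout["me_seq"]
            d = CutEndRead("r", THREE_PRIME, len(me), "x" * 20, me)
            tp = TrunkPlacement(
                d, "c1", "+", ((layout["a_start"], layout["a_end"]),), "+"
            )
            got = sorted(p.interval.start for p in rm.place_cut_segment(tp, d))
            expected = brute_force_segment_scan(
                genome, gene.span, tp.blocks, "+", THREE_PRIME, me
            )
            assert got == expected


class TestReconstruction:
    def _segment(self, start, end, unique=True):
        from mexh.cutend_remapper import SegmentPlacement

        return SegmentPlacement(
            GenomicInterval("c1", start, end, "+"), "AG", "GT",
            gap=30, within_gene=True, unique=unique,
        )

    def test_contiguous_trunk_plus_segment(self):
        tp = TrunkPlacement(None, "c1", "+", ((100, 196),), "+")
        from mexh.cutend_remapper import reconstruct_read

        aln = reconstruct_read(tp, self._segment(230, 235))
        assert aln.blocks == ((100, 196), (230, 235))
        assert aln.n_junctions == 1
        assert aln.source == "cutend_recovered"

    def test_spliced_trunk_plus_segment(self):
        tp = TrunkPlacement(None, "c1", "+", ((100, 150), (300, 346)), "+")
        from mexh.cutend_remapper import reconstruct_read

        aln = reconstruct_read(tp, self._segment(380, 385))
        assert len(aln.blocks) == 3 and aln.n_junctions == 2

    def test_overlapping_segment_rejected(self):
        tp = TrunkPlacement(None, "c1", "+", ((100, 196),), "+")
        from mexh.cutend_remapper import reconstruct_read

        with pytest.raises(ValueError):
            reconstruct_read(tp, self._segment(190, 195))

    def test_non_unique_segment_rejected(self):
        tp = TrunkPlacement(None, "c1", "+", ((100, 196),), "+")
        from mexh.cutend_remapper import reconstruct_read

        with pytest.raises(ValueError):
            reconstruct_read(tp, self._segment(230, 235, unique=False))


class TestCycles:
    def test_chained_read_recovered_in_second_cycle(self):
        genome, annotation, layout = microexon_gene(seed=23)
        cs = genome.contigs["c1"]
        me = layout["me_seq"]
        # Read A ends exactly at the microexon 3' boundary: cut-end
        # recoverable in cycle 1, which publishes the upstream junction.
        read_a = UnmappedRead("A", cs[layout["a_end"] - 55 : layout["a_end"]] + me)
        # Read B ends 3 nt into the microexon: needs that junction first.
        read_b = UnmappedRead("B", cs[layout["a_end"] - 57 : layout["a_end"]] + me[:3])
        rm = CutEndRemapper(genome, annotation)
        recovered, stats = rm.run_cycles([read_a, read_b], max_cycles=3)
        assert stats == [1, 1, 0]
        by_id = {a.read_id: a for a in recovered}
        assert by_id["A"].blocks == (
            (layout["a_end"] - 55, layout["a_end"]),
            (layout["me_start"], layout["me_end"]),
        )
        assert by_id["B"].blocks == (
            (layout["a_end"] - 57, layout["a_end"]),
            (layout["me_start"], layout["me_start"] + 3),
        )

    def test_no_recoverable_reads_stops_after_one_cycle(self, toy_locus):
        genome, annotation, *_ = toy_locus
        rm = CutEndRemapper(genome, annotation)
        junk = UnmappedRead("junk", rand_seq(np.random.default_rng(99), 60))
        recovered, stats = rm.run_cycles([junk], max_cycles=3)
        assert recovered == [] and stats == [0]

    def test_all_recoverable_in_first_cycle(self):
        genome, annotation, layout = microexon_gene(seed=29)
        cs = genome.contigs["c1"]
        me = layout["me_seq"]
        read_a = UnmappedRead("A", cs[layout["a_end"] - 55 : layout["a_end"]] + me)
        rm = CutEndRemapper(genome, annotation)
        recovered, stats = rm.run_cycles([read_a], max_cycles=3)
        assert stats == [1, 0] and len(recovered) == 1


class TestRecoveredInvariants:
    def test_recovered_reads_reproduce_parent_and_motifs(self, small_dataset, discovery):
        genome, *_ = small_dataset
        masked_by_id = {r.read_id: r for r in small_dataset[5]}
        cs = genome.contigs["chr1"]
        checked = 0
        for aln in discovery.recovered[:300]:
            read = masked_by_id[aln.read_id]
            placed = "".join(cs[s:e] for s, e in aln.blocks)
            expect = read.sequence
            assert placed in (expect, reverse_complement(expect))
            for j in aln.junctions(genome):
                assert 20 <= j.acceptor - j.donor <= 10_000
                motif = j.motif if aln.strand == "+" else reverse_complement(j.motif)
                assert motif[:2] == "GT" and motif[2:] == "AG"
            checked += 1
        assert checked > 50
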