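import numpy as np
import pytest
from hypothesis import given, strategies as st

from mexh.genome_io import GenomicInterval
from mexh.microexon_caller import MicroexonCandidate
from mexh.read_model import SplicedAlignment
from mexh.splicing_quant import (
    AS,
    CS,
    UNCLASSIFIED,
    TrioEvent,
    classify_as_cs,
    compute_psi,
    delta_psi,
    detect_trios,
    long_exon_comparison,
    tissue_specific,
)


def _event(counts):
    event = TrioEvent(
        GenomicInterval("c1", 100, 200, "+"),
        GenomicInterval("c1", 300, 312, "+"),
        GenomicInterval("c1", 400, 500, "+"),
    )
    event.counts = counts
    return event


class TestPsi:
    @pytest.mark.parametrize(
        "counts,psi",
        [
            ((10, 10, 0), 1.0),
            ((0, 0, 7), 0.0),
            ((4, 6, 5), 0.5),  # (4+6)/2 / ((4+6)/2 + 5)
            ((3, 3, 3), 0.5),
        ],
    )
    def test_averaged_inclusion_formula(self, counts, psi):
        rec = compute_psi(_event({"s": counts}), "s")
        assert rec.informative and rec.psi == pytest.approx(psi)

    def test_uninformative_when_denominator_zero(self):
        rec = compute_psi(_event({"s": (0, 0, 0)}), "s")
        assert not rec.informative and rec.psi is None

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
        st.integers(1, 10),
    )
    def test_monotone_in_inclusion_and_skip(self, up, down, skip, bump):
        base = compute_psi(_event({"s": (up, down, skip)}), "s")
        more_inc = compute_psi(_event({"s": (up + bump, down, skip)}), "s")
        more_skip = compute_psi(_event({"s": (up, down, skip + bump)}), "s")
        if base.informative:
            assert 0.0 <= base.psi <= 1.0
            assert more_inc.psi >= base.psi
            assert more_skip.psi <= base.psi


class TestAsCs:
    def _records(self, psis):
        event = _event({})
        recs = []
        for i, p in enumerate(psis):
            if p is None:
                counts = (0, 0, 0)
            else:
                counts = (int(p * 100), int(p * 100), int((1 - p) * 100))
            event.counts[f"s{i}"] = counts
            recs.append(compute_psi(event, f"s{i}"))
        return event, recs

    @pytest.mark.parametrize(
        "psis,expected",
        [
            ((1.0, 1.0, 1.0), CS),
            ((1.0, 0.4), AS),
            ((1.0, 0.0), AS),  # cross-sample disagreement
            ((0.5,), AS),
            ((0.0, 0.0), UNCLASSIFIED),  # inclusion never observed
            ((None, None), UNCLASSIFIED),
        ],
    )
    def test_classification(self, psis, expected):
        event, recs = self._records(psis)
        assert classify_as_cs(event, recs) == expected


class TestDeltaPsi:
    def test_threshold_behaviour(self):
        event = _event({"a": (80, 80, 20), "b": (70, 70, 30)})
        rec = delta_psi(event, "a", "b")
        assert rec.delta == pytest.approx(0.10)
        assert rec.significant
        event = _event({"a": (50, 50, 50), "b": (47, 47, 53)})
        assert not delta_psi(event, "a", "b").significant
        event = _event({"a": (10, 10, 10), "b": (10, 10, 10)})
        rec = delta_psi(event, "a", "b")
        assert rec.delta == 0.0 and not rec.significant

    def test_uninformative_sample_is_an_error(self):
        event = _event({"a": (10, 10, 0), "b": (0, 0, 0)})
        with pytest.raises(ValueError):
            delta_psi(event, "a", "b")

    def test_exact_boundary_is_not_significant(self):
        # |delta| == 0.05 exactly (up to float representation) stays below.
        event = _event({"a": (55, 55, 45), "b": (50, 50, 50)})
        rec = delta_psi(event, "a", "b")
        assert abs(rec.delta) == pytest.approx(0.05)
        assert not rec.significant


class TestTissueSpecific:
    def _ev(self, psis):
        counts = {
            s: (int(p * 100), int(p * 100), int((1 - p) * 100))
            for s, p in psis.items()
        }
        return _event(counts)

    def test_head_specific_event(self):
        ev = self._ev({"h1": 0.6, "h2": 0.7, "b1": 0.0, "g1": 0.02})
        groups = {"head": ["h1", "h2"], "body": ["b1"], "gonad": ["g1"]}
        assert tissue_specific([ev], groups) == [(ev, "head")]

    def test_leaky_other_group_blocks_call(self):
        ev = self._ev({"h1": 0.6, "b1": 0.2})
        assert tissue_specific([ev], {"head": ["h1"], "body": ["b1"]}) == []

    def test_single_group_yields_nothing(self):
        ev = self._ev({"h1": 0.6})
        assert tissue_specific([ev], {"head": ["h1"]}) == []


def _junction_read(rid, blocks, sample):
    return SplicedAlignment(rid, "c1", "+", blocks, sample=sample)


class TestTrios:
    def _candidate(self):
        return MicroexonCandidate(GenomicInterval("c1", 300, 312, "+"))

    def test_flanked_candidate_yields_one_trio(self):
        alns = [
            _junction_read("i1", ((150, 200), (300, 312), (400, 450)), "s1"),
            _junction_read("i2", ((160, 200), (300, 312), (400, 460)), "s1"),
            _junction_read("k1", ((150, 200), (400, 450)), "s1"),
        ]
        (event,) = detect_trios([self._candidate()], alns)
        assert event.counts["s1"] == (2, 2, 1)
        rec = compute_psi(event, "s1")
        assert rec.psi == pytest.approx(2 / 3)

    def test_candidate_without_upstream_flank_yields_no_trio(self):
        alns = [_junction_read("i", ((300, 312), (400, 450)), "s1")]
        assert detect_trios([self._candidate()], alns) == []

    def test_two_cassettes_between_same_flanks(self):
        c1 = MicroexonCandidate(GenomicInterval("c1", 300, 312, "+"))
        c2 = MicroexonCandidate(GenomicInterval("c1", 340, 350, "+"))
        alns = [
            _junction_read("a", ((150, 200), (300, 312), (400, 450)), "s1"),
            _junction_read("b", ((150, 200), (340, 350), (400, 450)), "s1"),
        ]
        assert len(detect_trios([c1, c2], alns)) == 2


def test_long_exons_constitutive_in_simulation(small_dataset, discovery):
    genome, annotation, truth, reads, mapped, masked = small_dataset
    alignments = [
        SplicedAlignment(r.read_id, r.contig, r.strand, r.blocks, sample=r.sample)
        for r in mapped
    ] + discovery.recovered
    result = long_exon_comparison(annotation, alignments)
    assert result["n_as"] + result["n_cs"] > 0
    # Normal exons are present in every isoform: none should look AS.
    assert result["as_fraction"] == pytest.approx(0.0)


def test_psi_recovers_designed_inclusion(small_dataset, discovery):
    """Estimated PSI tracks the designed inclusion level of planted events."""
    genome, annotation, truth, reads, mapped, masked = small_dataset
    alignments = [
        SplicedAlignment(r.read_id, r.contig, r.strand, r.blocks, sample=r.sample)
        for r in mapped
    ] + [
        SplicedAlignment(a.read_id, a.contig, a.strand, a.blocks, sample="s1")
        for a in discovery.recovered
    ]
    events = detect_trios(discovery.candidates, alignments, annotation, ["s1"])
    truth_by_key = truth.by_key()
    checked = 0
    deviations = []
    for event in events:
        me = truth_by_key.get(event.key)
        if me is None:
            continue
        rec = compute_psi(event, "s1")
        if not rec.informative:
            continue
        # Consistency: the pipeline's junction counts reproduce the truth
        # table's expected counts for the same final alignment set.
        el, er, es = me.expected_counts["s1"]
        expected_psi = ((el + er) / 2) / ((el + er) / 2 + es)
        assert rec.psi == pytest.approx(expected_psi, abs=0.05)
        deviations.append(abs(rec.psi - me.pi["s1"]))
        checked += 1
    assert checked >= 4
    assert np.mean(deviations) < 0.15  # tracks the designed inclusion levels
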