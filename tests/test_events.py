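"""Splice-event extraction, typing, deduplication and junction support."""

import pytest

from conftest import flip_strand, make_locus, make_tx, mirror_locus
from zygotx.events import (
    count_events,
    extract_events,
    extract_events_naive,
    skipping_read_support,
)
from zygotx.model import AlignedRead, GeneLocus, GenomicInterval, TranscriptModel


class TestSimpleUnits:
    def test_cassette_exon_gives_single_es(self, three_exon_locus):
        (ev,) = extract_events(three_exon_locus)
        assert ev.event_type == "ES"
        assert ev.n_skipped_exons == 1
        assert (ev.unit_start, ev.unit_end) == (200, 500)
        assert ev.variant_a == ()
        assert [(i.start, i.end) for i in ev.variant_b] == [(300, 400)]
        assert (ev.flank_upstream.start, ev.flank_upstream.end) == (100, 200)
        assert (ev.flank_downstream.start, ev.flank_downstream.end) == (500, 600)

    def test_double_skip_counts_two_exons(self):
        locus = make_locus(
            [(100, 200), (300, 400), (500, 600), (700, 800)],
            [(100, 200), (700, 800)],
        )
        (ev,) = extract_events(locus)
        assert (ev.event_type, ev.n_skipped_exons) == ("ES", 2)

    def test_internal_intron_retention(self):
        locus = make_locus(
            [(100, 200), (300, 400), (500, 600), (700, 800)],
            [(100, 200), (300, 600), (700, 800)],
        )
        (ev,) = extract_events(locus)
        assert ev.event_type == "IR"
        assert (ev.unit_start, ev.unit_end) == (300, 600)

    def test_terminal_intron_retention_is_not_an_internal_unit(self):
        # retained *last* intron has no bounding shared site downstream
        locus = make_locus(
            [(100, 200), (300, 400), (500, 600)],
            [(100, 200), (300, 600)],
        )
        assert extract_events(locus) == []

    @pytest.mark.parametrize(
        "strand,shift_end,expected",
        [
            ("+", True, "AD"),
            ("+", False, "AA"),
            ("-", True, "AA"),
            ("-", False, "AD"),
        ],
    )
    def test_boundary_shift_typing_is_strand_aware(self, strand, shift_end, expected):
        base = [(100, 200), (300, 400), (500, 600)]
        if shift_end:
            alt = [(100, 200), (300, 430), (500, 600)]
        else:
            alt = [(100, 200), (270, 400), (500, 600)]
        locus = make_locus(base, alt, strand=strand)
        (ev,) = extract_events(locus)
        assert ev.event_type == expected

    def test_alternative_first_exon_yields_no_splice_event(self):
        locus = make_locus(
            [(1000, 1100), (1300, 1400), (1600, 1700)],
            [(200, 330), (1300, 1400), (1600, 1700)],
        )
        assert extract_events(locus) == []

    def test_single_transcript_locus_has_no_events(self):
        assert extract_events(make_locus([(100, 200), (300, 400)])) == []


class TestProperties:
    def multi_locus(self):
        return make_locus(
            [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)],
            [(100, 200), (500, 600), (700, 800), (900, 1000)],  # ES at exon 2
            [(100, 200), (300, 400), (500, 600), (730, 800), (900, 1000)],  # AA
        )

    def test_events_deduplicated_across_pairs(self):
        events = extract_events(self.multi_locus())
        assert sorted(e.event_type for e in events) == ["AA", "ES"]

    def test_symmetric_in_transcript_order(self):
        locus = self.multi_locus()
        rev = GeneLocus(locus.gene_id, tuple(reversed(locus.transcripts)))
        assert extract_events(locus) == extract_events(rev)

    def test_translation_invariance(self):
        locus = self.multi_locus()
        off = 10_000
        moved = GeneLocus(
            locus.gene_id,
            tuple(
                TranscriptModel.from_exon_coords(
                    t.transcript_id,
                    t.gene_id,
                    t.chrom,
                    t.strand,
                    [(e.start + off, e.end + off) for e in t.exons],
                )
                for t in locus.transcripts
            ),
        )
        base = extract_events(locus)
        shifted = extract_events(moved)
        assert [
            (e.event_type, e.unit_start + off, e.unit_end + off) for e in base
        ] == [(e.event_type, e.unit_start, e.unit_end) for e in shifted]

    def test_strand_flip_swaps_aa_and_ad(self):
        ad_locus = make_locus(
            [(100, 200), (300, 400), (500, 600)],
            [(100, 200), (300, 430), (500, 600)],  # donor shift: AD on +
        )
        assert [e.event_type for e in extract_events(ad_locus)] == ["AD"]
        assert [e.event_type for e in extract_events(flip_strand(ad_locus))] == ["AA"]
        aa_locus = make_locus(
            [(100, 200), (300, 400), (500, 600)],
            [(100, 200), (270, 400), (500, 600)],  # acceptor shift: AA on +
        )
        assert [e.event_type for e in extract_events(aa_locus)] == ["AA"]
        assert [e.event_type for e in extract_events(flip_strand(aa_locus))] == ["AD"]
        # ES and IR are unchanged by the strand flip
        es_locus = make_locus(
            [(100, 200), (300, 400), (500, 600)], [(100, 200), (500, 600)]
        )
        assert [e.event_type for e in extract_events(flip_strand(es_locus))] == ["ES"]

    def test_reverse_orientation_mirror_preserves_event_types(self):
        # reflecting coordinates and flipping the strand rewrites the same
        # molecule, so every event keeps its type
        for locus in (self.multi_locus(),):
            fwd = sorted(e.event_type for e in extract_events(locus))
            mirrored = sorted(
                e.event_type for e in extract_events(mirror_locus(locus))
            )
            assert fwd == mirrored

    def test_agrees_with_naive_enumerator_on_hand_built_loci(self):
        for locus in (
            self.multi_locus(),
            mirror_locus(self.multi_locus()),
            make_locus([(0, 50), (100, 150)], [(0, 150)]),
        ):
            assert extract_events(locus) == extract_events_naive(locus)


class TestCountEvents:
    def test_empty_list_gives_zero_table(self):
        df = count_events([])
        assert df["count"].sum() == 0
        assert df["fraction"].sum() == 0

    def test_counts_and_fractions(self, three_exon_locus):
        es = extract_events(three_exon_locus)[0]
        ir_locus = make_locus(
            [(100, 200), (300, 400), (500, 600), (700, 800)],
            [(100, 200), (300, 600), (700, 800)],
        )
        ir = extract_events(ir_locus)[0]
        df = count_events([es, es, ir])
        assert df.loc["ES", "count"] == 2
        assert df.loc["IR", "fraction"] == pytest.approx(1 / 3)
        assert df["fraction"].sum() == pytest.approx(1.0)
        assert df.loc["ES", "n_single"] == 2


class TestSkippingReadSupport:
    def junction_read(self, rid, gap):
        return AlignedRead(
            rid,
            (
                GenomicInterval("chr1", gap[0] - 25, gap[0], "+"),
                GenomicInterval("chr1", gap[1], gap[1] + 25, "+"),
            ),
            "sim",
            50,
        )

    def test_no_reads_gives_zero(self, three_exon_locus):
        (ev,) = extract_events(three_exon_locus)
        assert skipping_read_support(ev, []) == 0

    def test_exact_gap_counts_and_mismatched_gap_does_not(self, three_exon_locus):
        (ev,) = extract_events(three_exon_locus)
        exact = self.junction_read("r1", (200, 500))
        inclusion = self.junction_read("r2", (200, 300))
        off_by_one = self.junction_read("r3", (200, 501))
        assert skipping_read_support(ev, [exact, inclusion, off_by_one]) == 1

    def test_rejects_non_es_events(self):
        ir_locus = make_locus(
            [(100, 200), (300, 400), (500, 600), (700, 800)],
            [(100, 200), (300, 600), (700, 800)],
        )
        (ev,) = extract_events(ir_locus)
        with pytest.raises(ValueError):
            skipping_read_support(ev, [])
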