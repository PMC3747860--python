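"""Synthetic-data generator: determinism, validity and planted dynamics."""

import numpy as np
import pytest

from zygotx import simulate
from zygotx.model import GeneLocus, GenomicInterval, TranscriptModel, exon_id


class TestGenerateAnnotation:
    def test_single_isoform_single_locus(self):
        loci, truth = simulate.generate_annotation(
            1, isoforms_per_locus={1: 1.0}, seed=7, ntr_fraction=0.0,
            extended_last_fraction=0.0,
        )
        assert len(loci) == 1 and len(loci[0].transcripts) == 1
        assert truth.planted_events == []

    def test_deterministic_for_a_seed(self):
        a_loci, a_truth = simulate.generate_annotation(50, seed=1)
        b_loci, b_truth = simulate.generate_annotation(50, seed=1)
        assert a_loci == b_loci
        assert a_truth.planted_events == b_truth.planted_events
        assert a_truth.planted_classes == b_truth.planted_classes
        c_loci, _ = simulate.generate_annotation(50, seed=2)
        assert c_loci != a_loci

    def test_truth_ids_exist_in_annotation(self):
        loci, truth = simulate.generate_annotation(80, seed=3)
        truth.validate(loci)  # raises on any dangling planted id

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_annotation(
                5, isoforms_per_locus={2: 1.0}, exon_count_range=(1, 1), seed=0
            )
        with pytest.raises(ValueError):
            simulate.generate_annotation(0, seed=0)

    def test_model_invariants_hold_everywhere(self):
        loci, _ = simulate.generate_annotation(60, seed=4)
        # constructors validate; touching derived fields exercises the chains
        for locus in loci:
            for t in locus.transcripts:
                assert all(i.length >= 1 for i in t.introns)
                assert t.span.length > 0


class TestSimulateReads:
    def test_depth_zero_gives_empty(self):
        loci, truth = simulate.generate_annotation(5, seed=5)
        assert simulate.simulate_reads(loci, truth, 0, "pre", seed=1) == []

    def test_invalid_condition_rejected(self):
        loci, truth = simulate.generate_annotation(2, seed=5)
        with pytest.raises(ValueError):
            simulate.simulate_reads(loci, truth, 10, "mid", seed=1)

    def test_single_exon_transcript_yields_contained_single_blocks(self):
        exon = GenomicInterval("chr1", 1000, 2000, "+")
        loci = [GeneLocus("g", (TranscriptModel("g.t0", "g", (exon,)),))]
        reads = simulate.simulate_reads(loci, simulate.TruthSet(), 100, "pre", seed=2)
        assert len(reads) == 100
        assert all(len(r.blocks) == 1 for r in reads)
        assert all(r.start >= 1000 and r.end <= 2000 for r in reads)

    def test_planted_skip_fraction_recovered_at_junctions(self):
        pairs = []
        from zygotx import evaluation

        pairs = evaluation.skip_fraction_errors(
            n_loci=12, depth=2000, fraction=0.5, seed=6
        )
        assert pairs, "generator planted no skip pairs"
        pooled = np.mean([m for _, m in pairs])
        assert abs(pooled - 0.5) < 0.05

    def test_planted_extension_shifts_three_prime_halves(self):
        loci, truth, _ = simulate.make_last_exon_cohort(
            n_exons=20, n_planted=20, seed=8
        )
        reads = simulate.simulate_reads(loci, truth, 400, "post", seed=9)
        from zygotx.utr import half_counts

        fracs = []
        for locus in loci:
            exon = locus.transcripts[0].last_exon
            first, last = half_counts(exon, [r for r in reads if r.chrom == exon.chrom
                                             and r.end > exon.start and r.start < exon.end])
            fracs.append(last / (first + last))
        assert abs(np.mean(fracs) - 0.75) < 0.03


class TestSimulatePeaks:
    def test_no_association_no_background_gives_nothing(self):
        loci, truth = simulate.generate_annotation(20, seed=10)
        peaks = simulate.simulate_peaks(
            loci, truth, association_prob=0.0, background_rate=0.0, seed=1
        )
        assert peaks == []

    def test_full_association_covers_every_planted_exon(self):
        loci, truth = simulate.generate_annotation(
            60, isoforms_per_locus={2: 1.0}, seed=11, ntr_fraction=0.0
        )
        peaks = simulate.simulate_peaks(
            loci, truth, association_prob=1.0, background_rate=0.0, seed=1
        )
        exons = {
            exon_id(e): e
            for locus in loci
            for t in locus.transcripts
            for e in t.exons
        }
        for eid in truth.planted_peak_associated_exons:
            e = exons[eid]
            assert any(
                p.interval.chrom == e.chrom
                and min(p.interval.end, e.end) > max(p.interval.start, e.start)
                for p in peaks
            )

    def test_association_fraction_matches_probability(self):
        loci, truth = simulate.generate_annotation(
            150, isoforms_per_locus={2: 0.2, 3: 0.8}, exon_count_range=(6, 8),
            seed=12, ntr_fraction=0.0, extended_last_fraction=0.0,
        )
        exons = sorted(
            {
                exon_id(e)
                for locus in loci
                for t in locus.transcripts
                for e in t.exons[1:-1]
            }
        )[:500]
        peaks = simulate.simulate_peaks(
            loci, truth, association_prob=0.6, background_rate=0.0, seed=13,
            associated_exons=exons,
        )
        lookup = {
            exon_id(e): e
            for locus in loci
            for t in locus.transcripts
            for e in t.exons
        }
        hit = 0
        for eid in exons:
            e = lookup[eid]
            if any(
                p.interval.chrom == e.chrom
                and min(p.interval.end, e.end) > max(p.interval.start, e.start)
                for p in peaks
            ):
                hit += 1
        assert abs(hit / len(exons) - 0.6) < 0.07

    def test_probability_bounds_validated(self):
        loci, truth = simulate.generate_annotation(2, seed=1)
        with pytest.raises(ValueError):
            simulate.simulate_peaks(loci, truth, association_prob=1.5)


class TestDerivedTables:
    def test_expression_from_reads_is_fpkm(self):
        loci, truth = simulate.generate_annotation(
            10, isoforms_per_locus={1: 1.0}, seed=14, ntr_fraction=0.0,
            extended_last_fraction=0.0,
        )
        reads = simulate.simulate_reads(loci, truth, 50, "pre", seed=15)
        expr = simulate.expression_from_reads(loci, reads, reads)
        t = loci[0].transcripts[0]
        expected = 50 / ((t.length / 1000) * (len(reads) / 1e6))
        assert expr.fpkm_pre(t.transcript_id) == pytest.approx(expected)

    def test_domain_table_realizes_planted_classes(self):
        from zygotx.io import domain_sets
        from zygotx.orfs import classify_domain_change

        loci, truth = simulate.generate_annotation(120, seed=16)
        df = simulate.domain_table(loci, truth, seed=17)
        sets = domain_sets(df)
        checked = 0
        for locus in loci:
            if locus.gene_id in truth.ntr_loci:
                continue
            base = locus.transcripts[0].transcript_id
            for t in locus.transcripts[1:]:
                planted = truth.planted_domain_changes[t.transcript_id]
                got = classify_domain_change(
                    sets.get(t.transcript_id, frozenset()),
                    sets.get(base, frozenset()),
                )
                assert got == planted
                checked += 1
        assert checked > 20

    def test_truth_json_round_trip_fields(self, tmp_path):
        import json

        loci, truth = simulate.generate_annotation(30, seed=18)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        payload = json.loads(path.read_text())
        assert len(payload["planted_events"]) == len(truth.planted_events)
        assert set(payload["planted_classes"]) == set(truth.planted_classes)
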