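"""Peak-TSS assignment, bidirectional promoters, enrichment and ChIP metagenes."""

import numpy as np
import pytest

from conftest import make_locus
from zygotx.epigenome import (
    assign_peaks_to_tss,
    chip_metagene,
    find_bidirectional_pairs,
    internal_exon_regions,
    overlap_enrichment,
    pair_expression_correlation,
    skipped_exon_triplet,
)
from zygotx.events import extract_events
from zygotx.model import (
    AlignedRead,
    ExpressionTable,
    GenomicInterval,
    Peak,
)


def peak(start, end, chrom="chr1", mark="H3K4me3"):
    return Peak(mark, GenomicInterval(chrom, start, end), 10.0)


class TestAssignPeaksToTss:
    def test_tss_inside_peak_assigned_at_distance_zero(self):
        ((p, genes),) = assign_peaks_to_tss(
            [peak(100, 600)], [("gA", "chr1", 300)], window=500
        )
        assert genes == ("gA",)

    def test_boundary_window_inclusive_and_strict_beyond(self):
        # last covered peak base is 599: 1099 is exactly 500 away, 1100 is 501
        tss = [("gNear", "chr1", 1099), ("gFar", "chr1", 1100)]
        ((_, genes),) = assign_peaks_to_tss([peak(100, 600)], tss, window=500)
        assert genes == ("gNear",)

    def test_matches_brute_force_all_pairs_scan(self):
        rng = np.random.default_rng(31)
        peaks = [
            peak(int(s), int(s) + int(rng.integers(100, 800)))
            for s in rng.integers(0, 50_000, size=40)
        ]
        tss = [
            (f"g{i}", "chr1", int(rng.integers(0, 52_000))) for i in range(60)
        ]
        got = assign_peaks_to_tss(peaks, tss, window=500)
        for p, genes in got:
            expected = sorted(
                gid
                for gid, _, pos in tss
                if max(p.interval.start - pos, pos - (p.interval.end - 1), 0) <= 500
            )
            assert list(genes) == expected


class TestBidirectionalPairs:
    def divergent_layout(self):
        # minus-strand gene ends (TSS) at 10_000; plus-strand gene starts at 10_500
        minus = make_locus([(8000, 10_000)], gid="gM", strand="-")
        plus = make_locus([(10_500, 12_000)], gid="gP", strand="+")
        return [minus, plus]

    def test_divergent_pair_detected(self):
        loci = self.divergent_layout()
        peaks = [peak(10_000, 10_400)]  # midpoint 10_200
        (pair,) = find_bidirectional_pairs(peaks, loci, window=1000)
        assert (pair.gene_minus, pair.gene_plus) == ("gM", "gP")
        assert pair.distance_minus == 200 and pair.distance_plus == 300

    def test_same_strand_genes_do_not_pair(self):
        loci = [
            make_locus([(8000, 10_000)], gid="gA", strand="+"),
            make_locus([(10_500, 12_000)], gid="gB", strand="+"),
        ]
        assert find_bidirectional_pairs([peak(10_000, 10_400)], loci) == []

    def test_convergent_orientation_rejected(self):
        # plus gene upstream, minus gene downstream: TSSs point towards each other
        loci = [
            make_locus([(8000, 10_000)], gid="gA", strand="+"),
            make_locus([(10_500, 12_000)], gid="gB", strand="-"),
        ]
        assert find_bidirectional_pairs([peak(9900, 10_600)], loci) == []

    def test_three_gene_layout_matches_hand_enumeration(self):
        loci = [
            make_locus([(8000, 10_000)], gid="gM1", strand="-"),
            make_locus([(9000, 10_100)], gid="gM2", strand="-"),
            make_locus([(10_500, 12_000)], gid="gP", strand="+"),
        ]
        pairs = find_bidirectional_pairs([peak(10_000, 10_400)], loci, window=1000)
        assert {(p.gene_minus, p.gene_plus) for p in pairs} == {
            ("gM1", "gP"),
            ("gM2", "gP"),
        }

    def test_output_invariant_under_gene_order(self):
        loci = self.divergent_layout()
        peaks = [peak(10_000, 10_400)]
        assert find_bidirectional_pairs(peaks, loci) == find_bidirectional_pairs(
            peaks, list(reversed(loci))
        )


class TestPairExpressionCorrelation:
    def pairs_and_loci(self, n=30, seed=32, anti=False, equal=False):
        rng = np.random.default_rng(seed)
        loci, pairs, expr = [], [], {}
        for i in range(n):
            base = 100_000 * (i + 1)
            minus = make_locus([(base, base + 2000)], gid=f"m{i}", strand="-")
            plus = make_locus([(base + 2500, base + 4000)], gid=f"p{i}", strand="+")
            loci += [minus, plus]
            x = float(rng.uniform(1, 50))
            y = x if equal else (60.0 - x if anti else float(rng.uniform(1, 50)))
            expr[f"m{i}.t0"] = (x, x)
            expr[f"p{i}.t0"] = (y, y)
            (pair,) = find_bidirectional_pairs(
                [peak(base + 2100, base + 2500)], [minus, plus]
            )
            pairs.append(pair)
        return pairs, loci, ExpressionTable(expr)

    def test_identical_expression_gives_one(self):
        pairs, loci, expr = self.pairs_and_loci(equal=True)
        assert pair_expression_correlation(pairs, loci, expr) == pytest.approx(1.0)

    def test_anticorrelated_expression_gives_minus_one(self):
        pairs, loci, expr = self.pairs_and_loci(anti=True)
        assert pair_expression_correlation(pairs, loci, expr) == pytest.approx(-1.0)

    def test_independent_expression_near_zero(self):
        pairs, loci, expr = self.pairs_and_loci(n=1000, seed=33)
        assert abs(pair_expression_correlation(pairs, loci, expr)) < 0.1

    def test_requires_three_pairs(self):
        pairs, loci, expr = self.pairs_and_loci(n=2)
        with pytest.raises(ValueError):
            pair_expression_correlation(pairs, loci, expr)


class TestOverlapEnrichment:
    def universe(self, n=50):
        return [
            GenomicInterval("chr1", 10_000 * i, 10_000 * i + 2000, "+")
            for i in range(1, n + 1)
        ]

    def test_no_peaks_gives_zero_everywhere(self):
        u = self.universe()
        enr = overlap_enrichment(u[:10], [], u, n_iterations=50, seed=0)
        assert enr.observed_overlaps == 0
        assert set(enr.null_draws) == {0}
        assert enr.empirical_p == 1.0

    def test_tiling_peaks_saturate(self):
        u = self.universe()
        peaks = [peak(0, 600_000, mark="H3K36me3")]
        enr = overlap_enrichment(u[:10], peaks, u, n_iterations=50, seed=0)
        assert enr.observed_overlaps == 10
        assert enr.empirical_p == 1.0

    def test_invariants_of_reported_statistics(self):
        rng = np.random.default_rng(34)
        u = self.universe(200)
        peaks = [
            peak(int(s), int(s) + 500, mark="H3K36me3")
            for s in rng.integers(0, 2_000_000, size=150)
        ]
        targets = [u[i] for i in rng.choice(200, size=40, replace=False)]
        enr = overlap_enrichment(targets, peaks, u, n_iterations=99, seed=1)
        assert enr.observed_overlaps <= enr.n_targets
        assert enr.null_mean == pytest.approx(np.mean(enr.null_draws))
        expected_p = (1 + sum(d >= enr.observed_overlaps for d in enr.null_draws)) / 100
        assert enr.empirical_p == pytest.approx(expected_p)
        assert 0 < enr.empirical_p <= 1

    def test_observed_monotone_as_peaks_added(self):
        rng = np.random.default_rng(35)
        u = self.universe(100)
        targets = [u[i] for i in range(20)]
        peaks = [
            peak(int(s), int(s) + 400, mark="H3K36me3")
            for s in rng.integers(0, 1_000_000, size=80)
        ]
        prev = -1
        for k in (0, 20, 40, 80):
            enr = overlap_enrichment(targets, peaks[:k], u, n_iterations=10, seed=2)
            assert enr.observed_overlaps >= prev
            prev = enr.observed_overlaps

    def test_target_outside_universe_rejected(self):
        u = self.universe()
        rogue = GenomicInterval("chr9", 0, 100, "+")
        with pytest.raises(ValueError):
            overlap_enrichment([rogue], [], u, n_iterations=10, seed=0)

    def test_universe_smaller_than_targets_rejected(self):
        u = self.universe(5)
        with pytest.raises(ValueError):
            overlap_enrichment(u * 2, [], u, n_iterations=10, seed=0)


class TestChipMetagene:
    def triplets(self):
        locus = make_locus(
            [(1000, 1400), (2000, 2300), (3000, 3500)],
            [(1000, 1400), (3000, 3500)],
        )
        (ev,) = extract_events(locus)
        return [skipped_exon_triplet(ev)]

    def uniform_reads(self, lo=500, hi=4000, n=4000, seed=36):
        rng = np.random.default_rng(seed)
        return [
            AlignedRead(
                f"c{i}",
                (GenomicInterval("chr1", int(s), int(s) + 50, ".") ,),
                "sim",
                50,
            )
            for i, s in enumerate(rng.integers(lo, hi, size=n))
        ]

    def test_chip_equal_to_input_gives_unit_ratio(self):
        reads = self.uniform_reads()
        profile = chip_metagene(
            self.triplets(), reads, reads, null_iterations=20, seed=3
        )
        assert np.allclose(profile.values, 1.0)
        assert profile.null_low is not None and len(profile.null_low) == 150

    def test_depth_scaling_cancels_in_rpm_ratio(self):
        reads = self.uniform_reads()
        doubled = reads + [
            AlignedRead(f"d{i}", r.blocks, "sim", 50) for i, r in enumerate(reads)
        ]
        profile = chip_metagene(
            self.triplets(), doubled, reads, null_iterations=5, seed=3
        )
        assert np.allclose(profile.values, 1.0)

    def test_internal_exon_regions_extend_to_flanking_introns(self):
        locus = make_locus([(1000, 1400), (2000, 2300), (3000, 3500)])
        ((exon, region),) = internal_exon_regions([locus])
        assert (exon.start, exon.end) == (2000, 2300)
        assert (region.start, region.end) == (1400, 3000)
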