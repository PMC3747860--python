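"""Histone-mark peaks vs transcript structure: peak-to-TSS assignment,
bidirectional promoters, bootstrap overlap enrichment and ChIP metagenes.

The enrichment test asks whether a target exon set (e.g. skipped exons)
co-localizes with peaks more than chance: each exon is extended to its
*event region* (start of the upstream intron to the end of the downstream
intron); a target counts as overlapped when that region shares >=1 bp with
any peak.  The null draws equally many exons uniformly *without replacement*
from the exon universe, many times; the empirical p-value is
``(1 + #draws >= observed) / (1 + n_iterations)`` and a 2x2 Pearson
chi-square (observed set vs pooled null draws, no continuity correction) is
reported alongside.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    AlignedRead,
    ExpressionTable,
    GeneLocus,
    GenomicInterval,
    Peak,
    ReadIndex,
    exon_id,
)
from .utr import MetageneProfile, bin_means


@dataclass(frozen=True)
class OverlapEnrichment:
    n_targets: int
    observed_overlaps: int
    null_draws: tuple[int, ...]
    null_mean: float
    chi_square_p: float
    empirical_p: float


@dataclass(frozen=True)
class BidirectionalPair:
    """Two divergent opposite-strand genes sharing one promoter peak."""

    peak: Peak
    gene_minus: str
    gene_plus: str
    tss_minus: int
    tss_plus: int
    distance_minus: int
    distance_plus: int


def _tss_to_interval_distance(pos: int, iv: GenomicInterval) -> int:
    if iv.contains(pos):
        return 0
    if pos < iv.start:
        return iv.start - pos
    return pos - (iv.end - 1)


def assign_peaks_to_tss(
    peaks: Sequence[Peak],
    tss_list: Sequence[tuple[str, str, int]],
    window: int = 500,
) -> list[tuple[Peak, tuple[str, ...]]]:
    """Assign each peak to every gene with a TSS within +-window of it.

    ``tss_list`` holds (gene_id, chrom, position) triples; the distance to a
    peak is 0 when the TSS falls inside the peak interval.  Returns one
    (peak, gene_ids) entry per input peak; unassigned peaks carry an empty
    tuple.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gid, chrom, pos in tss_list:
        by_chrom.setdefault(chrom, []).append((pos, gid))
    for lst in by_chrom.values():
        lst.sort()
    out = []
    for p in peaks:
        iv = p.interval
        cands = by_chrom.get(iv.chrom, [])
        positions = [pos for pos, _ in cands]
        lo = bisect.bisect_left(positions, iv.start - window)
        hi = bisect.bisect_right(positions, (iv.end - 1) + window)
        genes = sorted(
            gid
            for pos, gid in cands[lo:hi]
            if _tss_to_interval_distance(pos, iv) <= window
        )
        out.append((p, tuple(genes)))
    return out


def find_bidirectional_pairs(
    peaks: Sequence[Peak],
    loci: Sequence[GeneLocus],
    window: int = 1000,
) -> list[BidirectionalPair]:
    """Divergent gene pairs whose TSSs flank a promoter-mark peak.

    For each peak, every (minus-strand, plus-strand) gene pair with both
    TSSs within ``window`` of the peak midpoint and divergent orientation
    (the minus gene's TSS at or left of the plus gene's TSS, so each points
    away from the other) yields one pair.  A gene with several TSSs
    qualifies through the one closest to the peak midpoint.
    """
    gene_tss: dict[str, tuple[str, str, list[int]]] = {}
    for locus in loci:
        tsss = sorted({t.tss for t in locus.transcripts})
        gene_tss[locus.gene_id] = (locus.chrom, locus.strand, tsss)
    pairs = []
    for p in peaks:
        mid = p.midpoint
        minus, plus = [], []
        for gid, (chrom, strand, tsss) in sorted(gene_tss.items()):
            if chrom != p.interval.chrom:
                continue
            best = min(tsss, key=lambda t: (abs(t - mid), t))
            if abs(best - mid) > window:
                continue
            (minus if strand == "-" else plus).append((gid, best))
        for gm, tm in minus:
            for gp, tp in plus:
                if tm <= tp:
                    pairs.append(
                        BidirectionalPair(
                            p, gm, gp, tm, tp, abs(tm - mid), abs(tp - mid)
                        )
                    )
    return pairs


def gene_expression(
    loci: Sequence[GeneLocus], expression: ExpressionTable
) -> dict[str, tuple[float, float]]:
    """Per-gene FPKM as the sum over the gene's transcripts."""
    out = {}
    for locus in loci:
        pre = sum(expression.fpkm_pre(t.transcript_id) for t in locus.transcripts)
        post = sum(expression.fpkm_post(t.transcript_id) for t in locus.transcripts)
        out[locus.gene_id] = (pre, post)
    return out


def pair_expression_correlation(
    pairs: Sequence[BidirectionalPair],
    loci: Sequence[GeneLocus],
    expression: ExpressionTable,
    condition: str = "post",
) -> float:
    """Pearson correlation of expression across bidirectional gene pairs."""
    if condition not in ("pre", "post"):
        raise ValueError("condition must be 'pre' or 'post'")
    idx = 0 if condition == "pre" else 1
    gene_expr = gene_expression(loci, expression)
    xs, ys = [], []
    for pair in pairs:
        if pair.gene_minus in gene_expr and pair.gene_plus in gene_expr:
            xs.append(gene_expr[pair.gene_minus][idx])
            ys.append(gene_expr[pair.gene_plus][idx])
    if len(xs) < 3:
        raise ValueError("need >=3 pairs with expression for both genes")
    return float(stats.pearsonr(xs, ys)[0])


def internal_exon_regions(
    loci: Sequence[GeneLocus],
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """(exon, event region) for every distinct internal exon.

    The event region runs from the start of the upstream intron to the end
    of the downstream intron, i.e. from the end of the previous exon to the
    start of the next.
    """
    seen: dict[GenomicInterval, GenomicInterval] = {}
    for locus in loci:
        for t in locus.transcripts:
            for prev_e, e, next_e in zip(t.exons, t.exons[1:], t.exons[2:]):
                seen.setdefault(
                    e,
                    GenomicInterval(t.chrom, prev_e.end, next_e.start, t.strand),
                )
    return sorted(seen.items())


class _PeakOverlapIndex:
    def __init__(self, peaks: Sequence[Peak]):
        self._starts: dict[str, np.ndarray] = {}
        self._prefix_max_end: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            by_chrom.setdefault(p.interval.chrom, []).append(
                (p.interval.start, p.interval.end)
            )
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            self._starts[chrom] = starts
            self._prefix_max_end[chrom] = np.maximum.accumulate(ends)

    def overlaps_any(self, region: GenomicInterval) -> bool:
        starts = self._starts.get(region.chrom)
        if starts is None:
            return False
        k = int(np.searchsorted(starts, region.end, side="left"))
        return k > 0 and int(self._prefix_max_end[region.chrom][k - 1]) > region.start


def overlap_enrichment(
    target_regions: Sequence[GenomicInterval],
    peaks: Sequence[Peak],
    universe_regions: Sequence[GenomicInterval],
    n_iterations: int = 1000,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> OverlapEnrichment:
    """Bootstrap peak-overlap enrichment of a target region set.

    ``target_regions`` must be a coordinate subset of ``universe_regions``
    (both already extended to event regions).  See the module docstring for
    the null construction and reported statistics.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >=1")
    if len(universe_regions) < len(target_regions):
        raise ValueError("universe smaller than target set")
    universe_keys = {(r.chrom, r.start, r.end) for r in universe_regions}
    for r in target_regions:
        if (r.chrom, r.start, r.end) not in universe_keys:
            raise ValueError(f"target region {exon_id(r)} not in universe")
    if rng is None:
        rng = np.random.default_rng(seed)

    index = _PeakOverlapIndex(peaks)
    flags = np.array(
        [index.overlaps_any(r) for r in universe_regions], dtype=np.int64
    )
    observed = sum(index.overlaps_any(r) for r in target_regions)
    m, k = len(universe_regions), len(target_regions)
    # vectorized draws without replacement: the k smallest of m random keys
    keys = rng.random((n_iterations, m))
    chosen = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null_draws = flags[chosen].sum(axis=1)

    null_mean = float(null_draws.mean())
    null_total_ov = int(null_draws.sum())
    null_total = n_iterations * k
    table = np.array(
        [
            [observed, k - observed],
            [null_total_ov, null_total - null_total_ov],
        ]
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi_p = 1.0
    else:
        chi_p = float(stats.chi2_contingency(table, correction=False)[1])
    empirical_p = (1 + int((null_draws >= observed).sum())) / (1 + n_iterations)
    return OverlapEnrichment(
        n_targets=k,
        observed_overlaps=int(observed),
        null_draws=tuple(int(x) for x in null_draws),
        null_mean=null_mean,
        chi_square_p=chi_p,
        empirical_p=empirical_p,
    )


Triplet = tuple[GenomicInterval, GenomicInterval, GenomicInterval]


def skipped_exon_triplet(event) -> Triplet:
    """(upstream intron, skipped exon, downstream intron) of a single-ES event,
    in genomic orientation."""
    if event.event_type != "ES" or event.n_skipped_exons != 1:
        raise ValueError("triplet is defined for single exon-skipping events")
    exon = event.variant_b[0]
    up = GenomicInterval(event.chrom, event.unit_start, exon.start, event.strand)
    down = GenomicInterval(event.chrom, exon.end, event.unit_end, event.strand)
    return up, exon, down


def _triplet_profile(
    triplet: Triplet,
    chip_idx: ReadIndex,
    input_idx: ReadIndex,
    bins_per_segment: int,
    pseudocount: float,
) -> np.ndarray:
    chip_pm = chip_idx.total_reads / 1e6
    input_pm = input_idx.total_reads / 1e6
    strand = triplet[1].strand
    segs = triplet if strand != "-" else tuple(reversed(triplet))
    parts = []
    for seg in segs:
        chip = bin_means(chip_idx.coverage(seg), bins_per_segment) / chip_pm
        ctrl = bin_means(input_idx.coverage(seg), bins_per_segment) / input_pm
        if strand == "-":
            chip, ctrl = chip[::-1], ctrl[::-1]
        parts.append((chip + pseudocount) / (ctrl + pseudocount))
    return np.concatenate(parts)


def chip_metagene(
    triplets: Sequence[Triplet],
    chip_reads: Sequence[AlignedRead] | ReadIndex,
    input_reads: Sequence[AlignedRead] | ReadIndex,
    bins_per_segment: int = 50,
    null_iterations: int = 100,
    seed: int | None = 0,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> MetageneProfile:
    """ChIP/input ratio metagene over intron-exon-intron triplets.

    Each segment is rescaled to ``bins_per_segment`` bins 5'->3'
    (strand-aware); the per-bin signal is the ratio of reads-per-million
    tracks with a 0.5 pseudocount on both.  A null band (2.5th/97.5th
    percentile per bin) comes from ``null_iterations`` random placements of
    equal-size triplets over the covered chromosomes.
    """
    if not triplets:
        raise ValueError("metagene needs >=1 triplet")
    chip_idx = (
        chip_reads if isinstance(chip_reads, ReadIndex) else ReadIndex(chip_reads)
    )
    input_idx = (
        input_reads if isinstance(input_reads, ReadIndex) else ReadIndex(input_reads)
    )
    pseudo = 0.5
    acc = np.zeros(3 * bins_per_segment)
    for trip in triplets:
        acc += _triplet_profile(trip, chip_idx, input_idx, bins_per_segment, pseudo)
    values = acc / len(triplets)

    if chrom_sizes is None:
        chrom_sizes = {}
        for idx in (chip_idx, input_idx):
            for chrom, reads in idx._reads.items():  # noqa: SLF001
                end = max(r.end for r in reads)
                chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), end)
    chroms = sorted(chrom_sizes)
    rng = np.random.default_rng(seed)
    null_profiles = np.empty((null_iterations, 3 * bins_per_segment))
    sizes = [(t[0].length, t[1].length, t[2].length, t[1].strand) for t in triplets]
    for it in range(null_iterations):
        acc = np.zeros(3 * bins_per_segment)
        for l_up, l_ex, l_dn, strand in sizes:
            total = l_up + l_ex + l_dn
            chrom = chroms[rng.integers(len(chroms))]
            limit = max(1, chrom_sizes[chrom] - total)
            s = int(rng.integers(0, limit))
            trip = (
                GenomicInterval(chrom, s, s + l_up, strand),
                GenomicInterval(chrom, s + l_up, s + l_up + l_ex, strand),
                GenomicInterval(chrom, s + l_up + l_ex, s + total, strand),
            )
            acc += _triplet_profile(
                trip, chip_idx, input_idx, bins_per_segment, pseudo
            )
        null_profiles[it] = acc / len(sizes)
    low = np.percentile(null_profiles, 2.5, axis=0)
    high = np.percentile(null_profiles, 97.5, axis=0)
    return MetageneProfile(
        ("upstream_intron", "exon", "downstream_intron"),
        bins_per_segment,
        values,
        len(triplets),
        null_low=low,
        null_high=high,
    )
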