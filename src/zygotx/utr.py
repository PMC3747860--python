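"""3'-terminal-exon lengthening between conditions: the Q statistic.

A non-redundant database of strand-aware last exons (length > 400 bp, host
FPKM > 3 in both conditions) is scored by how strongly read coverage shifts
into the exon's 3' half after genome activation:

    p  = n_last / (n_first + n_last)          per condition
    Q  = (p2 - p1) * ln((FPKM_pre + FPKM_post) / 2)

where *first*/*last* are the strand-aware 5' and 3' halves of the exon and
p1/p2 the pre-/post- proportions.  A shift of reads towards the 3' half
after activation gives a positive Q, weighted by log mean expression so that
well-covered exons rank above noisy ones.  p is the bounded proportion (not
the first/last ratio) so empty halves stay finite and the sign keeps its
"more reads in the last part -> positive" reading.  The log base (natural)
only rescales Q and never changes the ranking.

Reads straddling the half boundary are assigned to the half containing the
midpoint of their overlap with the exon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    AlignedRead,
    ExpressionTable,
    GeneLocus,
    GenomicInterval,
    ReadIndex,
    exon_id,
)


@dataclass(frozen=True)
class QScoreRecord:
    exon: GenomicInterval
    transcript_ids: tuple[str, ...]
    n_first_pre: int
    n_last_pre: int
    n_first_post: int
    n_last_post: int
    p1: float
    p2: float
    fpkm_pre: float
    fpkm_post: float
    q: float

    @property
    def total_reads(self) -> int:
        return (
            self.n_first_pre + self.n_last_pre + self.n_first_post + self.n_last_post
        )


@dataclass(frozen=True)
class MetageneProfile:
    """Mean normalized signal over length-scaled features, 5'->3'."""

    segments: tuple[str, ...]
    bins_per_segment: int
    values: np.ndarray
    n_features: int
    null_low: Optional[np.ndarray] = None
    null_high: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("metagene needs >=1 feature")
        if len(self.values) != self.bins_per_segment * len(self.segments):
            raise ValueError("values length != bins x segments")


def build_last_exon_db(
    loci: Sequence[GeneLocus],
    expression: ExpressionTable,
    min_length: int = 400,
    min_fpkm: float = 3.0,
) -> list[tuple[GenomicInterval, tuple[str, ...]]]:
    """Non-redundant last exons passing the length and expression filters.

    Exact duplicate coordinates collapse to one entry listing every
    contributing transcript; the entry's FPKM (per condition) is the max
    over contributors and must exceed ``min_fpkm`` in *both* conditions.
    Length must strictly exceed ``min_length``.
    """
    collected: dict[GenomicInterval, list[str]] = {}
    for locus in loci:
        for t in locus.transcripts:
            collected.setdefault(t.last_exon, []).append(t.transcript_id)
    out = []
    for exon in sorted(collected):
        tids = tuple(sorted(collected[exon]))
        if exon.length <= min_length:
            continue
        fpkm_pre = max(expression.fpkm_pre(tid) for tid in tids)
        fpkm_post = max(expression.fpkm_post(tid) for tid in tids)
        if fpkm_pre > min_fpkm and fpkm_post > min_fpkm:
            out.append((exon, tids))
    return out


def _overlap_midpoint(read: AlignedRead, exon: GenomicInterval) -> Optional[int]:
    """Genomic position of the middle overlapping base, None if disjoint."""
    segs = []
    for b in read.blocks:
        s, e = max(b.start, exon.start), min(b.end, exon.end)
        if s < e:
            segs.append((s, e))
    total = sum(e - s for s, e in segs)
    if total == 0:
        return None
    target = total // 2
    for s, e in segs:
        if target < e - s:
            return s + target
        target -= e - s
    raise AssertionError("unreachable")


def half_counts(
    exon: GenomicInterval, reads: Iterable[AlignedRead]
) -> tuple[int, int]:
    """Reads in the strand-aware 5' and 3' halves of an exon.

    The exon splits at ``start + floor(length/2)``; each overlapping read
    goes to the half containing the midpoint of its overlap.
    """
    mid = exon.start + exon.length // 2
    left = right = 0
    for r in reads:
        if r.chrom != exon.chrom:
            continue
        pos = _overlap_midpoint(r, exon)
        if pos is None:
            continue
        if pos < mid:
            left += 1
        else:
            right += 1
    if exon.strand == "-":
        return right, left
    return left, right


def q_score(
    n_first_pre: int,
    n_last_pre: int,
    n_first_post: int,
    n_last_post: int,
    fpkm_pre: float,
    fpkm_post: float,
) -> tuple[float, float, float]:
    """(p1, p2, Q) for one last exon; raises on a read-free condition."""
    tot_pre = n_first_pre + n_last_pre
    tot_post = n_first_post + n_last_post
    if tot_pre == 0 or tot_post == 0:
        raise ValueError("no reads in one condition: record unscorable")
    p1 = n_last_pre / tot_pre
    p2 = n_last_post / tot_post
    q = (p2 - p1) * math.log((fpkm_pre + fpkm_post) / 2.0)
    return p1, p2, q


def score_last_exons(
    loci: Sequence[GeneLocus],
    expression: ExpressionTable,
    reads_pre: Sequence[AlignedRead] | ReadIndex,
    reads_post: Sequence[AlignedRead] | ReadIndex,
    min_length: int = 400,
    min_fpkm: float = 3.0,
) -> list[QScoreRecord]:
    """Build the last-exon database and score every scorable entry.

    Entries with zero overlapping reads in either condition are excluded
    (unscorable), matching the Q preconditions.
    """
    idx_pre = reads_pre if isinstance(reads_pre, ReadIndex) else ReadIndex(reads_pre)
    idx_post = (
        reads_post if isinstance(reads_post, ReadIndex) else ReadIndex(reads_post)
    )
    records = []
    for exon, tids in build_last_exon_db(loci, expression, min_length, min_fpkm):
        f_pre = max(expression.fpkm_pre(t) for t in tids)
        f_post = max(expression.fpkm_post(t) for t in tids)
        n1f, n1l = half_counts(exon, idx_pre.overlapping(exon))
        n2f, n2l = half_counts(exon, idx_post.overlapping(exon))
        try:
            p1, p2, q = q_score(n1f, n1l, n2f, n2l, f_pre, f_post)
        except ValueError:
            continue
        records.append(
            QScoreRecord(exon, tids, n1f, n1l, n2f, n2l, p1, p2, f_pre, f_post, q)
        )
    return records


def select_extended(
    records: Sequence[QScoreRecord], min_q: float = 0.0
) -> list[QScoreRecord]:
    """Records with Q above ``min_q``, strongest first.

    Ties resolve by total read count (descending), then coordinates, so the
    ranking does not depend on input order.
    """
    kept = [r for r in records if r.q > min_q]
    return sorted(
        kept,
        key=lambda r: (
            -r.q,
            -r.total_reads,
            r.exon.chrom,
            r.exon.start,
            r.exon.end,
        ),
    )


def records_to_rows(records: Sequence[QScoreRecord]) -> list[dict]:
    return [
        {
            "exon_id": exon_id(r.exon),
            "transcript_ids": ",".join(r.transcript_ids),
            "n_first_pre": r.n_first_pre,
            "n_last_pre": r.n_last_pre,
            "n_first_post": r.n_first_post,
            "n_last_post": r.n_last_post,
            "p1": round(r.p1, 6),
            "p2": round(r.p2, 6),
            "fpkm_pre": round(r.fpkm_pre, 6),
            "fpkm_post": round(r.fpkm_post, 6),
            "q": round(r.q, 6),
        }
        for r in records
    ]


def bin_means(values: np.ndarray, bins: int) -> np.ndarray:
    """Average a per-base track into ``bins`` equal-width bins.

    Features shorter than ``bins`` are sampled by nearest position so every
    feature contributes a full-length profile.
    """
    n = len(values)
    if n >= bins:
        edges = (np.arange(bins + 1) * n) // bins
        sums = np.add.reduceat(values, edges[:-1])
        widths = np.diff(edges)
        return sums / widths
    idx = (np.arange(bins) * n) // bins
    return values[idx].astype(np.float64)


def coverage_metagene(
    exons: Sequence[GenomicInterval],
    reads_pre: Sequence[AlignedRead] | ReadIndex,
    reads_post: Sequence[AlignedRead] | ReadIndex,
    bins: int = 100,
) -> tuple[MetageneProfile, MetageneProfile]:
    """Depth-normalized read coverage metagene over length-scaled exons.

    Each exon is rescaled to ``bins`` bins 5'->3' (strand-aware); per-bin
    mean coverage is divided by (total reads in the sample / 1e6) and
    averaged over exons.  Returns the (pre, post) profiles.
    """
    if not exons:
        raise ValueError("metagene needs >=1 exon")
    profiles = []
    for reads in (reads_pre, reads_post):
        idx = reads if isinstance(reads, ReadIndex) else ReadIndex(reads)
        acc = np.zeros(bins)
        for exon in exons:
            cov = idx.coverage(exon)
            if exon.strand == "-":
                cov = cov[::-1]
            acc += bin_means(cov, bins)
        per_million = idx.total_reads / 1e6
        values = acc / len(exons) / per_million
        profiles.append(
            MetageneProfile(("last_exon",), bins, values, len(exons))
        )
    return profiles[0], profiles[1]
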