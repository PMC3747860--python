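"""Classify assembled transcripts against a reference annotation and
enumerate per-locus TSS/TTS diversity.

Classification mirrors the conventional "class code" logic: a query is
*identical* to a reference transcript when their intron chains match exactly
(terminal exon ends are free, so assembly end-truncation does not create
false novelty), a *new_isoform* when it shares >=1 exonic base on the same
strand with some reference transcript but no intron chain, and an *NTR*
(novel transcribed region) when it has no same-strand exonic overlap with
the reference at all.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from .model import ExpressionTable, GeneLocus, TranscriptModel

CLASS_IDENTICAL = "identical"
CLASS_NEW_ISOFORM = "new_isoform"
CLASS_NTR = "NTR"


@dataclass(frozen=True)
class TranscriptClass:
    transcript_id: str
    transcript_class: str
    closest_reference_id: str = ""
    shared_bases: int = 0

    def __post_init__(self) -> None:
        if (self.transcript_class == CLASS_NTR) != (self.closest_reference_id == ""):
            raise ValueError("NTR iff no closest reference")


@dataclass(frozen=True)
class TssCluster:
    """A single-linkage cluster of transcript 5' (or 3') end coordinates."""

    locus_id: str
    members: tuple[int, ...]
    representative: int


def shared_exonic_bases(a: TranscriptModel, b: TranscriptModel) -> int:
    """Exonic bases two transcripts share (two-pointer over sorted exons)."""
    if a.chrom != b.chrom:
        return 0
    i = j = 0
    total = 0
    ea, eb = a.exons, b.exons
    while i < len(ea) and j < len(eb):
        lo = max(ea[i].start, eb[j].start)
        hi = min(ea[i].end, eb[j].end)
        if lo < hi:
            total += hi - lo
        if ea[i].end < eb[j].end:
            i += 1
        else:
            j += 1
    return total


class ReferenceIndex:
    """Span-sorted per-(chrom, strand) index over reference transcripts."""

    def __init__(self, reference: Iterable[GeneLocus]):
        by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
        for locus in reference:
            for t in locus.transcripts:
                by_key.setdefault((t.chrom, t.strand), []).append(t)
        self._tx: dict[tuple[str, str], list[TranscriptModel]] = {}
        self._starts: dict[tuple[str, str], list[int]] = {}
        self._maxspan: dict[tuple[str, str], int] = {}
        self.chroms = {chrom for chrom, _ in by_key}
        for key, txs in by_key.items():
            txs.sort(key=lambda t: (t.span.start, t.transcript_id))
            self._tx[key] = txs
            self._starts[key] = [t.span.start for t in txs]
            self._maxspan[key] = max(t.span.end - t.span.start for t in txs)

    def span_overlapping(self, query: TranscriptModel) -> list[TranscriptModel]:
        key = (query.chrom, query.strand)
        starts = self._starts.get(key)
        if starts is None:
            return []
        lo = bisect.bisect_left(starts, query.span.start - self._maxspan[key])
        hi = bisect.bisect_left(starts, query.span.end)
        return [t for t in self._tx[key][lo:hi] if t.span.end > query.span.start]


def classify_transcript(
    query: TranscriptModel, reference: ReferenceIndex | Sequence[GeneLocus]
) -> TranscriptClass:
    """Classify one assembled transcript against the reference annotation."""
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    if query.chrom not in index.chroms:
        warnings.warn(
            f"{query.transcript_id}: chromosome {query.chrom} absent from the "
            "reference; classifying as NTR",
            stacklevel=2,
        )
        return TranscriptClass(query.transcript_id, CLASS_NTR)
    overlapping = [
        (shared_exonic_bases(query, t), t)
        for t in index.span_overlapping(query)
    ]
    overlapping = [(n, t) for n, t in overlapping if n > 0]
    if not overlapping:
        return TranscriptClass(query.transcript_id, CLASS_NTR)
    chain = query.intron_chain
    matching = [
        (n, t) for n, t in overlapping if t.intron_chain == chain
    ]
    pool = matching if matching else overlapping
    n_best, best = min(pool, key=lambda item: (-item[0], item[1].transcript_id))
    cls = CLASS_IDENTICAL if matching else CLASS_NEW_ISOFORM
    return TranscriptClass(query.transcript_id, cls, best.transcript_id, n_best)


def classify_transcripts(
    queries: Iterable[GeneLocus], reference: Sequence[GeneLocus] | ReferenceIndex
) -> list[TranscriptClass]:
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    out = []
    for locus in queries:
        for t in locus.transcripts:
            out.append(classify_transcript(t, index))
    return out


def filter_expressed(
    loci: Sequence[GeneLocus],
    expression: ExpressionTable,
    threshold: float = 3.0,
) -> list[GeneLocus]:
    """Keep transcripts robustly expressed in at least one condition.

    A transcript survives iff ``max(fpkm_pre, fpkm_post) > threshold``
    (strict); loci with no surviving transcript are dropped.  Transcripts
    absent from the table count as FPKM 0.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    out = []
    for locus in loci:
        kept = tuple(
            t
            for t in locus.transcripts
            if max(expression.get(t.transcript_id)) > threshold
        )
        if kept:
            out.append(GeneLocus(locus.gene_id, kept))
    return out


def _cluster_coords(
    locus_id: str,
    coords: Sequence[int],
    strand: str,
    linkage_threshold: int,
) -> list[TssCluster]:
    """Single-linkage clustering of 1-D end coordinates.

    On a line, single linkage at threshold *d* is exactly: sort the unique
    coordinates and break wherever the gap between neighbours exceeds *d*.
    The representative is the coordinate used by the most transcripts; ties
    go to the most upstream member (smallest on '+', largest on '-').
    """
    counts: dict[int, int] = {}
    for c in coords:
        counts[c] = counts.get(c, 0) + 1
    uniq = sorted(counts)
    clusters: list[list[int]] = []
    for c in uniq:
        if clusters and c - clusters[-1][-1] <= linkage_threshold:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    out = []
    for members in clusters:
        upstream_key = (lambda c: c) if strand == "+" else (lambda c: -c)
        rep = min(members, key=lambda c: (-counts[c], upstream_key(c)))
        out.append(TssCluster(locus_id, tuple(members), rep))
    return out


def cluster_tss(locus: GeneLocus, linkage_threshold: int = 50) -> list[TssCluster]:
    """Cluster transcript 5' ends; the cluster count is the locus TSS count.

    ``linkage_threshold=0`` reproduces exact-identity counting.
    """
    return _cluster_coords(
        locus.gene_id,
        [t.tss for t in locus.transcripts],
        locus.strand,
        linkage_threshold,
    )


def cluster_tts(locus: GeneLocus, linkage_threshold: int = 50) -> list[TssCluster]:
    """Cluster transcript 3' ends (transcription termination sites)."""
    return _cluster_coords(
        locus.gene_id,
        [t.tts for t in locus.transcripts],
        locus.strand,
        linkage_threshold,
    )


def usage_switch_score(locus: GeneLocus, expression: ExpressionTable) -> float:
    """Isoform usage shift between conditions as the Jensen-Shannon distance.

    Returns sqrt(JSD) with base-2 logarithms between the two conditions'
    isoform relative-abundance vectors; 0 for proportional compositions,
    1 for a complete switch.
    """
    pre = np.array([expression.fpkm_pre(t.transcript_id) for t in locus.transcripts])
    post = np.array([expression.fpkm_post(t.transcript_id) for t in locus.transcripts])
    if pre.sum() <= 0 or post.sum() <= 0:
        raise ValueError(f"{locus.gene_id}: zero total FPKM in a condition")
    d = float(jensenshannon(pre, post, base=2))
    return 0.0 if np.isnan(d) else d
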