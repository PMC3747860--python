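"""Core genomic data model shared by every analysis stage.

All internal coordinates are 0-based, half-open ``[start, end)``.  GTF I/O
converts to/from the 1-based inclusive convention at the file boundary
(:mod:`zygotx.io`); BED stays 0-based half-open.

A :class:`TranscriptModel` is a strand-aware exon chain; introns, the
transcription start site (TSS) and termination site (TTS) are derived from
it.  The TSS is the start of the first exon on ``+`` and the (half-open) end
of the last exon on ``-``; the TTS is the opposite terminus.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval. ``strand`` is '+', '-' or '.' (unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_length(self, other) > 0


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def exon_id(iv: GenomicInterval) -> str:
    """Stable string identifier for an exon, e.g. ``chr1:100-250(+)``."""
    return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded transcript as an ordered, non-overlapping exon chain."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        object.__setattr__(self, "exons", tuple(self.exons))
        first = self.exons[0]
        if first.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: transcripts must be stranded")
        prev_end = -1
        for e in self.exons:
            if e.chrom != first.chrom or e.strand != first.strand:
                raise ValueError(
                    f"{self.transcript_id}: exons on mixed chrom/strand"
                )
            if e.start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping/adjacent"
                )
            prev_end = e.end

    @classmethod
    def from_exon_coords(
        cls,
        transcript_id: str,
        gene_id: str,
        chrom: str,
        strand: str,
        coords: Iterable[tuple[int, int]],
    ) -> "TranscriptModel":
        exons = tuple(
            GenomicInterval(chrom, s, e, strand)
            for s, e in sorted(coords)
        )
        return cls(transcript_id, gene_id, exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        """Spliced (mature) length in nucleotides."""
        return sum(e.length for e in self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((a.end, b.start) for a, b in zip(self.exons, self.exons[1:]))

    @property
    def tss(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def tts(self) -> int:
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    @property
    def last_exon(self) -> GenomicInterval:
        """The strand-aware 3'-terminal exon."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    def is_exonic(self, pos: int) -> bool:
        i = bisect.bisect_right([e.start for e in self.exons], pos) - 1
        return i >= 0 and self.exons[i].contains(pos)


@dataclass(frozen=True)
class GeneLocus:
    """All transcripts sharing one gene_id (the annotation's locus)."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: locus needs >=1 transcript")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        t0 = self.transcripts[0]
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"{self.gene_id}: transcript {t.transcript_id} has gene_id "
                    f"{t.gene_id}"
                )
            if t.chrom != t0.chrom or t.strand != t0.strand:
                raise ValueError(f"{self.gene_id}: mixed chrom/strand in locus")
        spans = sorted((t.span.start, t.span.end) for t in self.transcripts)
        reach = spans[0][1]
        for s, e in spans[1:]:
            if s > reach:
                raise ValueError(f"{self.gene_id}: transcript spans disconnected")
            reach = max(reach, e)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
            self.strand,
        )


@dataclass(frozen=True)
class AlignedRead:
    """A spliced read alignment: ordered blocks, gaps are splice junctions."""

    read_id: str
    blocks: tuple[GenomicInterval, ...]
    aligner_tag: str = ""
    matched_bases: int = 1
    mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"{self.read_id}: read needs >=1 block")
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.matched_bases < 1:
            raise ValueError(f"{self.read_id}: matched_bases must be >=1")
        if self.mismatches < 0:
            raise ValueError(f"{self.read_id}: negative mismatches")
        prev_end = -1
        chrom = self.blocks[0].chrom
        for b in self.blocks:
            if b.chrom != chrom:
                raise ValueError(f"{self.read_id}: blocks on mixed chromosomes")
            if b.start <= prev_end:
                raise ValueError(f"{self.read_id}: blocks unsorted or overlapping")
            prev_end = b.end

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        """Splice junctions as (donor-side end, acceptor-side start) pairs."""
        return tuple((a.end, b.start) for a, b in zip(self.blocks, self.blocks[1:]))


@dataclass(frozen=True)
class Peak:
    """A called peak for one histone mark (or any interval-valued signal)."""

    mark: str
    interval: GenomicInterval
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.mark:
            raise ValueError("peak mark must be non-empty")
        if self.score < 0:
            raise ValueError("peak score must be non-negative")

    @property
    def midpoint(self) -> int:
        return (self.interval.start + self.interval.end) // 2


class ExpressionTable:
    """Per-transcript FPKM in the two conditions (pre- and post-ZGA).

    Missing transcripts read as (0, 0): a transcript the quantifier did not
    report is treated as unexpressed.
    """

    def __init__(self, records: Mapping[str, tuple[float, float]]):
        data: dict[str, tuple[float, float]] = {}
        for tid, (pre, post) in records.items():
            if pre < 0 or post < 0:
                raise ValueError(f"{tid}: negative FPKM")
            data[tid] = (float(pre), float(post))
        self._data = data

    def get(self, transcript_id: str) -> tuple[float, float]:
        return self._data.get(transcript_id, (0.0, 0.0))

    def fpkm_pre(self, transcript_id: str) -> float:
        return self.get(transcript_id)[0]

    def fpkm_post(self, transcript_id: str) -> float:
        return self.get(transcript_id)[1]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._data

    def __len__(self) -> int:
        return len(self._data)

    def items(self) -> Iterator[tuple[str, tuple[float, float]]]:
        return iter(sorted(self._data.items()))


class ReadIndex:
    """Sorted per-chromosome index over aligned reads for window queries."""

    def __init__(self, reads: Iterable[AlignedRead]):
        by_chrom: dict[str, list[AlignedRead]] = {}
        n = 0
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r)
            n += 1
        self.total_reads = n
        self._starts: dict[str, list[int]] = {}
        self._reads: dict[str, list[AlignedRead]] = {}
        self._maxspan: dict[str, int] = {}
        for chrom, rs in by_chrom.items():
            rs.sort(key=lambda r: (r.start, r.end, r.read_id))
            self._reads[chrom] = rs
            self._starts[chrom] = [r.start for r in rs]
            self._maxspan[chrom] = max(r.end - r.start for r in rs)

    def overlapping(self, region: GenomicInterval) -> list[AlignedRead]:
        """All reads whose span overlaps ``region`` (block-level filtering is
        left to the caller; spans suffice for short reads)."""
        starts = self._starts.get(region.chrom)
        if starts is None:
            return []
        reads = self._reads[region.chrom]
        lo = bisect.bisect_left(starts, region.start - self._maxspan[region.chrom])
        hi = bisect.bisect_left(starts, region.end)
        return [r for r in reads[lo:hi] if r.end > region.start]

    def coverage(self, region: GenomicInterval) -> np.ndarray:
        """Per-base read coverage over ``region`` counted from blocks."""
        cov = np.zeros(region.length, dtype=np.float64)
        for r in self.overlapping(region):
            for b in r.blocks:
                s = max(b.start, region.start) - region.start
                e = min(b.end, region.end) - region.start
                if s < e:
                    cov[s:e] += 1.0
        return cov
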