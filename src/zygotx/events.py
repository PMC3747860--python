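"""Alternative-splicing event extraction and quantification.

Events are extracted pairwise between the transcripts of a locus and then
deduplicated.  For each transcript pair, the genomic region where both have
aligned structure (the intersection of their spans) is scanned for *shared
splice sites* — positions that are an exon/intron boundary of the same kind
in both transcripts.  Every maximal stretch between two consecutive shared
sites where the internal structures differ is one *variation unit*, emitted
as a single typed event:

ES  exon skipping      one transcript splices straight across >=1 complete
                       internal exon(s) of the other
AA  alternative acceptor  the 3' (strand-aware) boundary of a shared intron
                       differs
AD  alternative donor  the 5' boundary differs
IR  intron retention   an intron of one transcript lies inside an exon of
                       the other

Variation at the transcript termini (alternative first/last exons, TSS and
TTS shifts) is deliberately not emitted here: those are handled as
structural isoform differences elsewhere, not as splice events.

Units matching several patterns at once are typed by the fixed precedence
ES > IR > AD > AA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import AlignedRead, GeneLocus, GenomicInterval, TranscriptModel

EVENT_TYPES = ("ES", "AA", "AD", "IR")

# splice-site kinds in genomic orientation: "end" = exon->intron boundary
# (donor on '+', acceptor on '-'); "start" = intron->exon boundary.
_END = "end"
_START = "start"

Site = tuple[int, str]


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing variation unit between two shared splice sites.

    ``flank_upstream``/``flank_downstream`` are the common exonic segments
    adjacent to the unit, in *genomic* orientation (upstream = lower
    coordinates).  ``variant_a``/``variant_b`` are the exonic intervals each
    variant places strictly inside the unit ``(unit_start, unit_end)``;
    variant_a is the structure with fewer exonic pieces (the skip side of an
    ES event is the empty tuple).
    """

    event_type: str
    locus_id: str
    chrom: str
    strand: str
    unit_start: int
    unit_end: int
    flank_upstream: GenomicInterval
    flank_downstream: GenomicInterval
    variant_a: tuple[GenomicInterval, ...]
    variant_b: tuple[GenomicInterval, ...]
    n_skipped_exons: int = 0

    @property
    def key(self) -> tuple:
        return (
            self.event_type,
            self.chrom,
            self.strand,
            self.unit_start,
            self.unit_end,
            tuple((i.start, i.end) for i in self.variant_a),
            tuple((i.start, i.end) for i in self.variant_b),
        )

    @property
    def skip_junction(self) -> tuple[int, int]:
        """The (donor-end, acceptor-start) gap of the exon-excluding junction."""
        if self.event_type != "ES":
            raise ValueError("skip_junction is defined for ES events only")
        return (self.unit_start, self.unit_end)


def _internal_sites(t: TranscriptModel) -> list[Site]:
    sites: list[Site] = []
    for intr in t.intron_chain:
        sites.append((intr[0], _END))
        sites.append((intr[1], _START))
    return sites


def _exonic_within(t: TranscriptModel, lo: int, hi: int) -> tuple[GenomicInterval, ...]:
    out = []
    for e in t.exons:
        s, ee = max(e.start, lo), min(e.end, hi)
        if s < ee:
            out.append(GenomicInterval(t.chrom, s, ee, t.strand))
    return tuple(out)


def _classify_unit(
    ka: str,
    kb: str,
    in1: Sequence[Site],
    in2: Sequence[Site],
    strand: str,
    t1: TranscriptModel,
    t2: TranscriptModel,
) -> tuple[str, int]:
    """Type a variation unit; returns (event_type, n_skipped_exons)."""
    if not in1 or not in2:
        inner = list(in1 or in2)
        kinds = [k for _, k in inner]
        if ka == _END and kb == _START:
            # empty side splices straight across; other side has complete exons
            if kinds == [_START, _END] * (len(inner) // 2):
                return "ES", len(inner) // 2
        elif ka == _START and kb == _END:
            if kinds == [_END, _START] * (len(inner) // 2):
                return "IR", 0
        return _classify_complex(in1, in2, strand, t1, t2)
    if len(in1) == 1 and len(in2) == 1 and in1[0][1] == in2[0][1]:
        kind = in1[0][1]
        if kind == _END:
            return ("AD" if strand == "+" else "AA"), 0
        return ("AA" if strand == "+" else "AD"), 0
    return _classify_complex(in1, in2, strand, t1, t2)


def _complete_exons(sites: Sequence[Site]) -> list[tuple[int, int]]:
    out = []
    for (p1, k1), (p2, k2) in zip(sites, sites[1:]):
        if k1 == _START and k2 == _END:
            out.append((p1, p2))
    return out


def _inner_introns(sites: Sequence[Site]) -> list[tuple[int, int]]:
    out = []
    for (p1, k1), (p2, k2) in zip(sites, sites[1:]):
        if k1 == _END and k2 == _START:
            out.append((p1, p2))
    return out


def _classify_complex(
    in1: Sequence[Site],
    in2: Sequence[Site],
    strand: str,
    t1: TranscriptModel,
    t2: TranscriptModel,
) -> tuple[str, int]:
    # precedence ES > IR > AD > AA for units matching several patterns
    best_skip = 0
    for sites, other in (((in1), t2), ((in2), t1)):
        n = sum(
            1
            for s, e in _complete_exons(sites)
            if not other.is_exonic(s) and not other.is_exonic(e - 1)
        )
        best_skip = max(best_skip, n)
    if best_skip:
        return "ES", best_skip
    for sites, other in ((in1, t2), (in2, t1)):
        for s, e in _inner_introns(sites):
            if other.is_exonic(s) and other.is_exonic(e - 1):
                return "IR", 0
    donor_kind = _END if strand == "+" else _START
    all_kinds = {k for _, k in list(in1) + list(in2)}
    if donor_kind in all_kinds:
        return "AD", 0
    return "AA", 0


def _flank_left(
    t1: TranscriptModel, t2: TranscriptModel, pa: int, ka: str,
    in1: Sequence[Site], in2: Sequence[Site], pb: int,
) -> GenomicInterval:
    chrom, strand = t1.chrom, t1.strand
    if ka == _END:
        e1 = next(e for e in t1.exons if e.end == pa)
        e2 = next(e for e in t2.exons if e.end == pa)
        return GenomicInterval(chrom, max(e1.start, e2.start), pa, strand)
    first_inner = min((p for p, _ in list(in1) + list(in2)), default=pb)
    return GenomicInterval(chrom, pa, first_inner, strand)


def _flank_right(
    t1: TranscriptModel, t2: TranscriptModel, pb: int, kb: str,
    in1: Sequence[Site], in2: Sequence[Site], pa: int,
) -> GenomicInterval:
    chrom, strand = t1.chrom, t1.strand
    if kb == _START:
        e1 = next(e for e in t1.exons if e.start == pb)
        e2 = next(e for e in t2.exons if e.start == pb)
        return GenomicInterval(chrom, pb, min(e1.end, e2.end), strand)
    last_inner = max((p for p, _ in list(in1) + list(in2)), default=pa)
    return GenomicInterval(chrom, last_inner, pb, strand)


def _canonical_variants(
    v1: tuple[GenomicInterval, ...], v2: tuple[GenomicInterval, ...]
) -> tuple[tuple[GenomicInterval, ...], tuple[GenomicInterval, ...]]:
    key = lambda v: (len(v), tuple((i.start, i.end) for i in v))
    return tuple(sorted((v1, v2), key=key))  # type: ignore[return-value]


def build_event(
    t1: TranscriptModel,
    t2: TranscriptModel,
    a: Site,
    b: Site,
    in1: Sequence[Site],
    in2: Sequence[Site],
    locus_id: str,
) -> ASEvent:
    """Assemble the canonical :class:`ASEvent` for one variation unit."""
    (pa, ka), (pb, kb) = a, b
    etype, n_skip = _classify_unit(ka, kb, in1, in2, t1.strand, t1, t2)
    v1 = _exonic_within(t1, pa, pb)
    v2 = _exonic_within(t2, pa, pb)
    va, vb = _canonical_variants(v1, v2)
    return ASEvent(
        event_type=etype,
        locus_id=locus_id,
        chrom=t1.chrom,
        strand=t1.strand,
        unit_start=pa,
        unit_end=pb,
        flank_upstream=_flank_left(t1, t2, pa, ka, in1, in2, pb),
        flank_downstream=_flank_right(t1, t2, pb, kb, in1, in2, pa),
        variant_a=va,
        variant_b=vb,
        n_skipped_exons=n_skip,
    )


def _pair_units(
    t1: TranscriptModel, t2: TranscriptModel
) -> list[tuple[Site, Site, list[Site], list[Site]]]:
    rs = max(t1.span.start, t2.span.start)
    re = min(t1.span.end, t2.span.end)
    if rs >= re:
        return []
    s1 = [s for s in _internal_sites(t1) if rs < s[0] < re]
    s2 = [s for s in _internal_sites(t2) if rs < s[0] < re]
    shared = sorted(set(s1) & set(s2))
    units = []
    for a, b in zip(shared, shared[1:]):
        in1 = [s for s in s1 if a[0] < s[0] < b[0]]
        in2 = [s for s in s2 if a[0] < s[0] < b[0]]
        if in1 or in2:
            units.append((a, b, in1, in2))
    return units


def _sort_events(events: Iterable[ASEvent]) -> list[ASEvent]:
    return sorted(
        events, key=lambda e: (e.chrom, e.unit_start, e.unit_end, e.event_type)
    )


def extract_events(locus: GeneLocus) -> list[ASEvent]:
    """All deduplicated splice events among the transcripts of one locus."""
    seen: dict[tuple, ASEvent] = {}
    for t1, t2 in combinations(locus.transcripts, 2):
        for a, b, in1, in2 in _pair_units(t1, t2):
            ev = build_event(t1, t2, a, b, in1, in2, locus.gene_id)
            seen.setdefault(ev.key, ev)
    return _sort_events(seen.values())


def extract_events_naive(locus: GeneLocus) -> list[ASEvent]:
    """Exhaustive per-base reference extractor used for validation.

    Builds boolean exon masks over the pairwise span intersection, finds
    shared transitions by scanning the masks, and re-derives each variation
    unit from them.  Mechanically independent from the interval algebra in
    :func:`extract_events`; intended for small loci.
    """
    seen: dict[tuple, ASEvent] = {}
    for t1, t2 in combinations(locus.transcripts, 2):
        rs = max(t1.span.start, t2.span.start)
        re = min(t1.span.end, t2.span.end)
        if rs >= re:
            continue
        n = re - rs
        m1 = np.zeros(n + 2, dtype=bool)
        m2 = np.zeros(n + 2, dtype=bool)
        # position p in genome maps to index p-rs+1; sentinel padding uses
        # the true exonic state just outside the region so transitions at
        # the region edges are not misread as splice sites.
        m1[0], m1[-1] = t1.is_exonic(rs - 1), t1.is_exonic(re)
        m2[0], m2[-1] = t2.is_exonic(rs - 1), t2.is_exonic(re)
        for e in t1.exons:
            s, ee = max(e.start, rs), min(e.end, re)
            if s < ee:
                m1[s - rs + 1 : ee - rs + 1] = True
        for e in t2.exons:
            s, ee = max(e.start, rs), min(e.end, re)
            if s < ee:
                m2[s - rs + 1 : ee - rs + 1] = True

        def transitions(m: np.ndarray) -> list[Site]:
            d = np.diff(m.astype(np.int8))
            sites: list[Site] = []
            for idx in np.nonzero(d)[0]:
                pos = rs + int(idx)  # genomic position of the boundary
                sites.append((pos, _START if d[idx] > 0 else _END))
            return sites

        s1, s2 = transitions(m1), transitions(m2)
        # keep only true internal splice sites (not transcript termini)
        term1 = {t1.span.start, t1.span.end}
        term2 = {t2.span.start, t2.span.end}
        s1 = [s for s in s1 if s[0] not in term1 and rs < s[0] < re]
        s2 = [s for s in s2 if s[0] not in term2 and rs < s[0] < re]
        shared = sorted(set(s1) & set(s2))
        for a, b in zip(shared, shared[1:]):
            in1 = [s for s in s1 if a[0] < s[0] < b[0]]
            in2 = [s for s in s2 if a[0] < s[0] < b[0]]
            if not in1 and not in2:
                continue
            ev = build_event(t1, t2, a, b, in1, in2, locus.gene_id)
            seen.setdefault(ev.key, ev)
    return _sort_events(seen.values())


def count_events(events: Sequence[ASEvent]) -> pd.DataFrame:
    """Summary table of event counts and fractions by type.

    The returned frame is indexed by event type with columns ``count`` and
    ``fraction`` (fractions over all events, summing to 1 when any exist)
    plus ``n_single``/``n_multi`` splitting ES events by the number of
    skipped exons.
    """
    counts = {t: 0 for t in EVENT_TYPES}
    n_single = n_multi = 0
    for ev in events:
        counts[ev.event_type] += 1
        if ev.event_type == "ES":
            if ev.n_skipped_exons == 1:
                n_single += 1
            else:
                n_multi += 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "count": [counts[t] for t in EVENT_TYPES],
            "fraction": [
                counts[t] / total if total else 0.0 for t in EVENT_TYPES
            ],
            "n_single": [n_single if t == "ES" else 0 for t in EVENT_TYPES],
            "n_multi": [n_multi if t == "ES" else 0 for t in EVENT_TYPES],
        },
        index=pd.Index(EVENT_TYPES, name="event_type"),
    )
    return df


def skipping_read_support(event: ASEvent, reads: Iterable[AlignedRead]) -> int:
    """Number of reads whose splice gap exactly matches the skip junction."""
    if event.event_type != "ES":
        raise ValueError("read support is defined for ES events")
    junction = event.skip_junction
    n = 0
    for r in reads:
        if r.chrom != event.chrom:
            continue
        if junction in r.gaps:
            n += 1
    return n


def events_to_frame(
    events: Sequence[ASEvent],
    support_pre: Sequence[int] | None = None,
    support_post: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Flatten events (one row each) for TSV output."""

    def fmt(ivs: tuple[GenomicInterval, ...]) -> str:
        return ",".join(f"{i.start}-{i.end}" for i in ivs) or "."

    rows = []
    for i, ev in enumerate(events):
        rows.append(
            {
                "event_type": ev.event_type,
                "locus_id": ev.locus_id,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "unit_start": ev.unit_start,
                "unit_end": ev.unit_end,
                "flank_upstream": f"{ev.flank_upstream.start}-{ev.flank_upstream.end}",
                "flank_downstream": (
                    f"{ev.flank_downstream.start}-{ev.flank_downstream.end}"
                ),
                "variant_a": fmt(ev.variant_a),
                "variant_b": fmt(ev.variant_b),
                "n_skipped_exons": ev.n_skipped_exons,
                "support_pre": support_pre[i] if support_pre is not None else 0,
                "support_post": support_post[i] if support_post is not None else 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_type",
            "locus_id",
            "chrom",
            "strand",
            "unit_start",
            "unit_end",
            "flank_upstream",
            "flank_downstream",
            "variant_a",
            "variant_b",
            "n_skipped_exons",
            "support_pre",
            "support_post",
        ],
    )
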