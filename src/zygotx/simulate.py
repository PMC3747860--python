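"""Synthetic annotation, read, expression, peak and domain-table generator.

Every structure the downstream analyses look for is *planted* with known
coordinates and recorded in a :class:`TruthSet`, so each stage has an
end-to-end recovery test: multi-isoform loci differing by cassette exons,
shifted donors/acceptors, retained introns, or distinct first/last exons;
condition-specific inclusion/skip read ratios over cassette junctions;
last exons whose read coverage shifts into the 3' half after genome
activation; and peaks preferentially placed over a chosen exon subset.

All generators are pure functions of (parameters, seed): one explicit
NumPy Generator per call, no global state.  Read length defaults to 50 nt,
the short-read regime the pipeline targets; length only matters for
junction spanning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .events import ASEvent
from .model import (
    AlignedRead,
    ExpressionTable,
    GeneLocus,
    GenomicInterval,
    Peak,
    TranscriptModel,
    exon_id,
)

_CHROMS = ("chr1", "chr2", "chr3", "chr4")

CLASS_IDENTICAL = "identical"
CLASS_NEW_ISOFORM = "new_isoform"
CLASS_NTR = "NTR"

_DOMAIN_CLASSES = ("all_retained", "some_lost", "all_lost", "gained")
_DOMAIN_CLASS_P = (0.62, 0.20, 0.16, 0.02)

_MOD_KINDS = ("es", "ir", "end_shift", "start_shift", "alt_first", "alt_last")
_MOD_WEIGHTS = {
    "es": 0.30,
    "ir": 0.14,
    "end_shift": 0.13,
    "start_shift": 0.13,
    "alt_first": 0.15,
    "alt_last": 0.15,
}


@dataclass(frozen=True)
class SkipPair:
    """Bookkeeping for one planted exon-skipping isoform pair."""

    locus_id: str
    inclusion_tid: str
    skip_tid: str
    chrom: str
    junction: tuple[int, int]  # gap of the exon-excluding (skip) junction
    inclusion_junction: tuple[int, int]  # gap into the first skipped exon
    exon_ids: tuple[str, ...]
    fraction_pre: float
    fraction_post: float

    def fraction(self, condition: str) -> float:
        return self.fraction_pre if condition == "pre" else self.fraction_post


@dataclass
class TruthSet:
    """Everything the generator planted, keyed the way each stage reports it."""

    planted_extended_last_exons: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    extended_hosts: dict[str, tuple[float, float]] = field(default_factory=dict)
    planted_skipped_exons: dict[str, dict[str, float]] = field(default_factory=dict)
    skip_pairs: dict[str, SkipPair] = field(default_factory=dict)
    planted_peak_associated_exons: set[str] = field(default_factory=set)
    planted_domain_changes: dict[str, str] = field(default_factory=dict)
    planted_tss_switches: set[str] = field(default_factory=set)
    planted_classes: dict[str, str] = field(default_factory=dict)
    planted_events: list[ASEvent] = field(default_factory=list)
    ntr_loci: set[str] = field(default_factory=set)

    def validate(self, loci: Sequence[GeneLocus]) -> None:
        """Check every planted id exists in the generated annotation."""
        tids = {t.transcript_id for l in loci for t in l.transcripts}
        gids = {l.gene_id for l in loci}
        eids = {exon_id(e) for l in loci for t in l.transcripts for e in t.exons}
        for eid in list(self.planted_extended_last_exons) + list(
            self.planted_skipped_exons
        ):
            if eid not in eids:
                raise ValueError(f"planted exon {eid} absent from annotation")
        for eid in self.planted_peak_associated_exons:
            if eid not in eids:
                raise ValueError(f"planted exon {eid} absent from annotation")
        for tid in list(self.extended_hosts) + list(self.planted_domain_changes):
            if tid not in tids:
                raise ValueError(f"planted transcript {tid} absent")
        for gid in list(self.planted_tss_switches) + list(self.ntr_loci):
            if gid not in gids:
                raise ValueError(f"planted locus {gid} absent")
        for probs in self.planted_extended_last_exons.values():
            if not all(0 <= p <= 1 for p in probs):
                raise ValueError("planted proportion outside [0, 1]")
        for fracs in self.planted_skipped_exons.values():
            if not all(0 <= f <= 1 for f in fracs.values()):
                raise ValueError("planted skip fraction outside [0, 1]")

    def to_json(self, path) -> None:
        def iv(i: GenomicInterval) -> list:
            return [i.chrom, i.start, i.end, i.strand]

        payload = {
            "planted_extended_last_exons": self.planted_extended_last_exons,
            "extended_hosts": self.extended_hosts,
            "planted_skipped_exons": self.planted_skipped_exons,
            "skip_pairs": {
                k: {
                    "locus_id": sp.locus_id,
                    "inclusion_tid": sp.inclusion_tid,
                    "skip_tid": sp.skip_tid,
                    "chrom": sp.chrom,
                    "junction": list(sp.junction),
                    "inclusion_junction": list(sp.inclusion_junction),
                    "exon_ids": list(sp.exon_ids),
                    "fraction_pre": sp.fraction_pre,
                    "fraction_post": sp.fraction_post,
                }
                for k, sp in sorted(self.skip_pairs.items())
            },
            "planted_peak_associated_exons": sorted(
                self.planted_peak_associated_exons
            ),
            "planted_domain_changes": self.planted_domain_changes,
            "planted_tss_switches": sorted(self.planted_tss_switches),
            "planted_classes": self.planted_classes,
            "ntr_loci": sorted(self.ntr_loci),
            "planted_events": [
                {
                    "event_type": e.event_type,
                    "locus_id": e.locus_id,
                    "chrom": e.chrom,
                    "strand": e.strand,
                    "unit_start": e.unit_start,
                    "unit_end": e.unit_end,
                    "flank_upstream": iv(e.flank_upstream),
                    "flank_downstream": iv(e.flank_downstream),
                    "variant_a": [iv(i) for i in e.variant_a],
                    "variant_b": [iv(i) for i in e.variant_b],
                    "n_skipped_exons": e.n_skipped_exons,
                }
                for e in self.planted_events
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _canonical_variants(v1, v2):
    key = lambda v: (len(v), tuple((i.start, i.end) for i in v))
    return tuple(sorted((v1, v2), key=key))


def _feasible_mods(
    n_ex: int, reserved: set[int], used_kinds: set[str]
) -> dict[str, list]:
    """Modification kinds applicable to a base exon chain, with their slots."""
    out: dict[str, list] = {}
    if "es" not in used_kinds:
        slots = []
        for n_skip in (1, 2):
            for i in range(1, n_ex - n_skip):
                touched = set(range(i - 1, i + n_skip + 1))
                if i + n_skip <= n_ex - 1 and not touched & reserved:
                    slots.append((i, n_skip))
        if slots:
            out["es"] = slots
    if "ir" not in used_kinds:
        slots = [
            j
            for j in range(1, n_ex - 2)
            if not {j, j + 1} & reserved
        ]
        if slots:
            out["ir"] = slots
    if "end_shift" not in used_kinds:
        slots = [
            j for j in range(1, n_ex - 1) if not {j, j + 1} & reserved
        ]
        if slots:
            out["end_shift"] = slots
    if "start_shift" not in used_kinds:
        slots = [
            j for j in range(0, n_ex - 2) if not {j, j + 1} & reserved
        ]
        if slots:
            out["start_shift"] = slots
    if n_ex >= 2:
        if "alt_first" not in used_kinds:
            out["alt_first"] = [None]
        if "alt_last" not in used_kinds:
            out["alt_last"] = [None]
    return out


def generate_annotation(
    n_loci: int,
    isoforms_per_locus: Optional[Mapping[int, float]] = None,
    exon_count_range: tuple[int, int] = (3, 8),
    seed: int = 0,
    ntr_fraction: float = 0.1,
    extended_last_fraction: float = 0.15,
    extension_p: tuple[float, float] = (0.5, 0.75),
    skip_fraction: tuple[float, float] = (0.3, 0.6),
    exon_length_range: tuple[int, int] = (120, 400),
    intron_length_range: tuple[int, int] = (200, 1500),
    extended_exon_length_range: tuple[int, int] = (600, 2000),
) -> tuple[list[GeneLocus], TruthSet]:
    """Generate a multi-isoform annotation with planted, recorded structure.

    Each extra isoform of a locus differs from the base isoform by exactly
    one of: cassette exon(s) (single or double skip), a shifted internal
    donor or acceptor, a retained intron, a distinct first exon (TSS switch)
    or a distinct last exon.  Modifications never touch the same or adjacent
    exons, so the planted events are exactly the variation units a pairwise
    extractor should find.  Deterministic for a given seed.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if isoforms_per_locus is None:
        isoforms_per_locus = {1: 0.25, 2: 0.50, 3: 0.25}
    iso_counts = sorted(isoforms_per_locus)
    iso_p = np.array([isoforms_per_locus[k] for k in iso_counts], dtype=float)
    if (iso_p < 0).any() or iso_p.sum() <= 0:
        raise ValueError("invalid isoform count distribution")
    iso_p = iso_p / iso_p.sum()
    lo_ex, hi_ex = exon_count_range
    if lo_ex < 1 or hi_ex < lo_ex:
        raise ValueError("invalid exon_count_range")
    if max(iso_counts) > 1 and hi_ex < 2:
        raise ValueError(
            "multi-isoform loci need >=2 exons to differ by a splice structure"
        )

    rng = np.random.default_rng(seed)
    truth = TruthSet()
    loci: list[GeneLocus] = []
    cursors = {c: 10_000 for c in _CHROMS}
    weights = dict(_MOD_WEIGHTS)

    for li in range(n_loci):
        gid = f"gene{li:05d}"
        chrom = _CHROMS[li % len(_CHROMS)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.choice(iso_counts, p=iso_p))
        is_ntr = rng.random() < ntr_fraction
        n_ex = int(rng.integers(lo_ex, hi_ex + 1))

        plant_extension = (
            n_iso == 1
            and n_ex >= 1
            and rng.random() < extended_last_fraction
        )
        exon_lens = rng.integers(
            exon_length_range[0], exon_length_range[1] + 1, size=n_ex
        )
        if plant_extension:
            three_prime_idx = n_ex - 1 if strand == "+" else 0
            exon_lens[three_prime_idx] = rng.integers(
                extended_exon_length_range[0], extended_exon_length_range[1] + 1
            )
        intron_lens = (
            rng.integers(
                intron_length_range[0], intron_length_range[1] + 1, size=n_ex - 1
            )
            if n_ex > 1
            else np.array([], dtype=int)
        )

        # 2500 bp margin on both sides leaves room for distinct first/last exons
        start = cursors[chrom] + 2500
        exons = []
        pos = start
        for k in range(n_ex):
            exons.append(
                GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand)
            )
            pos = exons[-1].end + (int(intron_lens[k]) if k < n_ex - 1 else 0)
        base = TranscriptModel(f"{gid}.t0", gid, tuple(exons))

        transcripts = [base]
        reserved: set[int] = set()
        used_kinds: set[str] = set()
        for j in range(1, n_iso):
            feas = _feasible_mods(n_ex, reserved, used_kinds)
            if not feas:
                break
            kinds = sorted(feas)
            p = np.array([weights[k] for k in kinds])
            kind = str(rng.choice(kinds, p=p / p.sum()))
            tid = f"{gid}.t{j}"
            sib, event = _apply_modification(
                kind, base, tid, feas[kind], rng, reserved, truth,
                skip_fraction=skip_fraction,
            )
            used_kinds.add(kind)
            transcripts.append(sib)
            if event is not None:
                truth.planted_events.append(event)

        locus = GeneLocus(gid, tuple(transcripts))
        loci.append(locus)
        cursors[chrom] = locus.span.end + 2500

        if is_ntr:
            truth.ntr_loci.add(gid)
            for t in locus.transcripts:
                truth.planted_classes[t.transcript_id] = CLASS_NTR
        else:
            truth.planted_classes[base.transcript_id] = CLASS_IDENTICAL
            for t in locus.transcripts[1:]:
                truth.planted_classes[t.transcript_id] = CLASS_NEW_ISOFORM
                truth.planted_domain_changes[t.transcript_id] = str(
                    rng.choice(_DOMAIN_CLASSES, p=_DOMAIN_CLASS_P)
                )

        if plant_extension:
            eid = exon_id(base.last_exon)
            truth.planted_extended_last_exons[eid] = extension_p
            truth.extended_hosts[base.transcript_id] = extension_p

    truth.planted_events.sort(
        key=lambda e: (e.chrom, e.unit_start, e.unit_end, e.event_type)
    )
    return loci, truth


def _apply_modification(
    kind: str,
    base: TranscriptModel,
    tid: str,
    slots: list,
    rng: np.random.Generator,
    reserved: set[int],
    truth: TruthSet,
    skip_fraction: tuple[float, float],
) -> tuple[TranscriptModel, Optional[ASEvent]]:
    E = base.exons
    chrom, strand, gid = base.chrom, base.strand, base.gene_id
    mk = lambda s, e: GenomicInterval(chrom, s, e, strand)

    if kind == "es":
        i, n_skip = slots[int(rng.integers(len(slots)))]
        reserved.update(range(i - 1, i + n_skip + 1))
        skipped = E[i : i + n_skip]
        sib = TranscriptModel(tid, gid, E[: i] + E[i + n_skip :])
        pa, pb = E[i - 1].end, E[i + n_skip].start
        event = ASEvent(
            "ES", gid, chrom, strand, pa, pb,
            flank_upstream=E[i - 1],
            flank_downstream=E[i + n_skip],
            variant_a=(),
            variant_b=tuple(skipped),
            n_skipped_exons=n_skip,
        )
        pair = SkipPair(
            locus_id=gid,
            inclusion_tid=base.transcript_id,
            skip_tid=tid,
            chrom=chrom,
            junction=(pa, pb),
            inclusion_junction=(pa, skipped[0].start),
            exon_ids=tuple(exon_id(e) for e in skipped),
            fraction_pre=skip_fraction[0],
            fraction_post=skip_fraction[1],
        )
        truth.skip_pairs[gid] = pair
        for e in skipped:
            truth.planted_skipped_exons[exon_id(e)] = {
                "pre": skip_fraction[0],
                "post": skip_fraction[1],
            }
            truth.planted_peak_associated_exons.add(exon_id(e))
        return sib, event

    if kind == "ir":
        j = int(slots[int(rng.integers(len(slots)))])
        reserved.update({j, j + 1})
        merged = mk(E[j].start, E[j + 1].end)
        sib = TranscriptModel(tid, gid, E[: j] + (merged,) + E[j + 2 :])
        pa, pb = E[j].start, E[j + 1].end
        va, vb = _canonical_variants(
            (mk(pa, pb),),
            (mk(pa, E[j].end), mk(E[j + 1].start, pb)),
        )
        event = ASEvent(
            "IR", gid, chrom, strand, pa, pb,
            flank_upstream=mk(pa, E[j].end),
            flank_downstream=mk(E[j + 1].start, pb),
            variant_a=va,
            variant_b=vb,
        )
        return sib, event

    if kind in ("end_shift", "start_shift"):
        j = int(slots[int(rng.integers(len(slots)))])
        reserved.update({j, j + 1})
        delta = int(rng.integers(6, 61)) * (1 if rng.random() < 0.5 else -1)
        if kind == "end_shift":
            new_end = E[j].end + delta
            moved = mk(E[j].start, new_end)
            sib = TranscriptModel(tid, gid, E[: j] + (moved,) + E[j + 1 :])
            pa, pb = E[j].start, E[j + 1].start
            va, vb = _canonical_variants((mk(pa, E[j].end),), (mk(pa, new_end),))
            etype = "AD" if strand == "+" else "AA"
            event = ASEvent(
                etype, gid, chrom, strand, pa, pb,
                flank_upstream=mk(pa, min(E[j].end, new_end)),
                flank_downstream=E[j + 1],
                variant_a=va,
                variant_b=vb,
            )
        else:
            new_start = E[j + 1].start + delta
            moved = mk(new_start, E[j + 1].end)
            sib = TranscriptModel(tid, gid, E[: j + 1] + (moved,) + E[j + 2 :])
            pa, pb = E[j].end, E[j + 1].end
            va, vb = _canonical_variants(
                (mk(E[j + 1].start, pb),), (mk(new_start, pb),)
            )
            etype = "AA" if strand == "+" else "AD"
            event = ASEvent(
                etype, gid, chrom, strand, pa, pb,
                flank_upstream=E[j],
                flank_downstream=mk(max(E[j + 1].start, new_start), pb),
                variant_a=va,
                variant_b=vb,
            )
        return sib, event

    if kind in ("alt_first", "alt_last"):
        # a distinct terminal exon beyond the base terminus: a TSS or TTS
        # switch, not a splice event
        five_prime = (kind == "alt_first") == (strand == "+")
        new_len = int(rng.integers(120, 301))
        gap = int(rng.integers(400, 1201))
        if five_prime:
            idx = 0
            new_exon = mk(E[0].start - gap - new_len, E[0].start - gap)
            exons = (new_exon,) + E[1:]
            reserved.add(0)
        else:
            idx = len(E) - 1
            new_exon = mk(E[-1].end + gap, E[-1].end + gap + new_len)
            exons = E[:-1] + (new_exon,)
            reserved.add(len(E) - 1)
        sib = TranscriptModel(tid, gid, exons)
        if kind == "alt_first":
            truth.planted_tss_switches.add(gid)
        return sib, None

    raise ValueError(f"unknown modification kind {kind!r}")


def split_reference(
    loci: Sequence[GeneLocus], truth: TruthSet
) -> list[GeneLocus]:
    """The reference annotation: base isoforms of the non-NTR loci."""
    out = []
    for locus in loci:
        if locus.gene_id in truth.ntr_loci:
            continue
        out.append(GeneLocus(locus.gene_id, (locus.transcripts[0],)))
    return out


@dataclass
class ReadSimReport:
    """Generation-side tallies for exact recovery checks."""

    reads_per_transcript: dict[str, int] = field(default_factory=dict)
    junction_counts: dict[tuple[str, int, int], int] = field(default_factory=dict)


def _map_read(
    t: TranscriptModel, offset: int, rlen: int
) -> tuple[GenomicInterval, ...]:
    """Map a spliced-coordinate read (genomic left-to-right) onto exon blocks."""
    blocks = []
    remaining = rlen
    pos = offset
    for e in t.exons:
        if pos >= e.length:
            pos -= e.length
            continue
        take = min(remaining, e.length - pos)
        blocks.append(
            GenomicInterval(t.chrom, e.start + pos, e.start + pos + take, t.strand)
        )
        remaining -= take
        pos = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError(f"read of length {rlen} at {offset} exceeds transcript")
    return tuple(blocks)


def simulate_reads(
    loci: Sequence[GeneLocus],
    truth: TruthSet,
    depth_per_transcript: int,
    condition: str,
    seed: int = 0,
    read_length: int = 50,
    return_report: bool = False,
):
    """Simulate short spliced reads honouring the planted dynamics.

    Reads are uniform over each transcript's spliced length.  For a planted
    exon-skipping pair the combined depth of the two isoforms is allocated
    per read with probability proportional to ``fraction x effective
    length``, so the planted fraction is what junction-spanning reads report
    in expectation.  For a planted extended last exon, reads are confined to
    that exon with the planted probability of landing in its 3' half.
    Read ids are ``<transcript>|<condition>|<i>``.
    """
    if condition not in ("pre", "post"):
        raise ValueError("condition must be 'pre' or 'post'")
    if depth_per_transcript < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    reads: list[AlignedRead] = []
    report = ReadSimReport()

    def emit(t: TranscriptModel, blocks, serial: int) -> None:
        rid = f"{t.transcript_id}|{condition}|{serial}"
        r = AlignedRead(rid, blocks, "sim", sum(b.length for b in blocks), 0)
        reads.append(r)
        report.reads_per_transcript[t.transcript_id] = (
            report.reads_per_transcript.get(t.transcript_id, 0) + 1
        )
        for gap in r.gaps:
            key = (t.chrom, gap[0], gap[1])
            report.junction_counts[key] = report.junction_counts.get(key, 0) + 1

    def emit_uniform(t: TranscriptModel, n: int) -> None:
        rlen = min(read_length, t.length)
        offsets = rng.integers(0, t.length - rlen + 1, size=n)
        for i, off in enumerate(offsets):
            emit(t, _map_read(t, int(off), rlen), i)

    for locus in loci:
        by_tid = {t.transcript_id: t for t in locus.transcripts}
        handled: set[str] = set()
        pair = truth.skip_pairs.get(locus.gene_id)
        if pair is not None and depth_per_transcript > 0:
            f = pair.fraction(condition)
            incl, skip = by_tid[pair.inclusion_tid], by_tid[pair.skip_tid]
            rlen = min(read_length, min(incl.length, skip.length))
            w_skip = f * (skip.length - rlen + 1)
            w_incl = (1 - f) * (incl.length - rlen + 1)
            n_total = 2 * depth_per_transcript
            n_skip = (
                int(rng.binomial(n_total, w_skip / (w_skip + w_incl)))
                if (w_skip + w_incl) > 0
                else 0
            )
            emit_uniform(skip, n_skip)
            emit_uniform(incl, n_total - n_skip)
            handled = {incl.transcript_id, skip.transcript_id}
        for t in locus.transcripts:
            if t.transcript_id in handled or depth_per_transcript == 0:
                continue
            p_shift = truth.extended_hosts.get(t.transcript_id)
            if p_shift is not None:
                p = p_shift[0] if condition == "pre" else p_shift[1]
                le = t.last_exon
                mid = le.start + le.length // 2
                left = (le.start, mid)
                right = (mid, le.end)
                three, five = (right, left) if t.strand == "+" else (left, right)
                rlen = min(read_length, mid - le.start, le.end - mid)
                in_three = rng.random(depth_per_transcript) < p
                for i, hit in enumerate(in_three):
                    lo, hi = three if hit else five
                    s = int(rng.integers(lo, hi - rlen + 1))
                    emit(t, (GenomicInterval(t.chrom, s, s + rlen, t.strand),), i)
            else:
                emit_uniform(t, depth_per_transcript)

    reads.sort(key=lambda r: (r.chrom, r.start, r.read_id))
    if return_report:
        return reads, report
    return reads


def simulate_peaks(
    loci: Sequence[GeneLocus],
    truth: TruthSet,
    association_prob: float = 0.8,
    background_rate: float = 0.1,
    seed: int = 0,
    peak_width: int = 500,
    mark: str = "H3K36me3",
    associated_exons: Optional[Iterable[str]] = None,
) -> list[Peak]:
    """Place peaks over planted-associated exons plus uniform background.

    Each exon in ``associated_exons`` (default: the truth's planted set)
    receives a peak centred on it with probability ``association_prob``;
    background peaks land uniformly over each chromosome's annotated span at
    ``background_rate`` per kb (Poisson).
    """
    if not (0 <= association_prob <= 1):
        raise ValueError("association_prob must be in [0, 1]")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = np.random.default_rng(seed)
    exon_lookup: dict[str, GenomicInterval] = {}
    spans: dict[str, list[int]] = {}
    for locus in loci:
        for t in locus.transcripts:
            for e in t.exons:
                exon_lookup[exon_id(e)] = e
        spans.setdefault(locus.chrom, [locus.span.start, locus.span.end])
        spans[locus.chrom][0] = min(spans[locus.chrom][0], locus.span.start)
        spans[locus.chrom][1] = max(spans[locus.chrom][1], locus.span.end)

    peaks: list[Peak] = []
    targets = (
        sorted(associated_exons)
        if associated_exons is not None
        else sorted(truth.planted_peak_associated_exons)
    )
    for eid in targets:
        if rng.random() >= association_prob:
            continue
        e = exon_lookup[eid]
        center = (e.start + e.end) // 2
        s = max(0, center - peak_width // 2)
        peaks.append(
            Peak(
                mark,
                GenomicInterval(e.chrom, s, s + peak_width),
                float(np.round(rng.uniform(3, 30), 3)),
            )
        )
    for chrom in sorted(spans):
        lo, hi = spans[chrom]
        lo, hi = max(0, lo - 1000), hi + 1000
        lam = background_rate * (hi - lo) / 1000.0
        n_bg = int(rng.poisson(lam))
        starts = np.sort(rng.integers(lo, max(lo + 1, hi - peak_width), size=n_bg))
        for s in starts:
            peaks.append(
                Peak(
                    mark,
                    GenomicInterval(chrom, int(s), int(s) + peak_width),
                    float(np.round(rng.uniform(3, 30), 3)),
                )
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def expression_from_reads(
    loci: Sequence[GeneLocus],
    reads_pre: Sequence[AlignedRead],
    reads_post: Sequence[AlignedRead],
) -> ExpressionTable:
    """FPKM per transcript from simulated read counts.

    Simulated read ids carry their source transcript, so counting is exact;
    FPKM = count / (spliced kb x million mapped reads in the sample).
    """
    def counts(reads: Sequence[AlignedRead]) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in reads:
            tid = r.read_id.split("|")[0]
            out[tid] = out.get(tid, 0) + 1
        return out

    c_pre, c_post = counts(reads_pre), counts(reads_post)
    m_pre = max(len(reads_pre), 1) / 1e6
    m_post = max(len(reads_post), 1) / 1e6
    table = {}
    for locus in loci:
        for t in locus.transcripts:
            kb = t.length / 1000.0
            table[t.transcript_id] = (
                c_pre.get(t.transcript_id, 0) / (kb * m_pre),
                c_post.get(t.transcript_id, 0) / (kb * m_post),
            )
    return ExpressionTable(table)


def domain_table(
    loci: Sequence[GeneLocus], truth: TruthSet, seed: int = 0
) -> pd.DataFrame:
    """Protein-domain coordinate table realizing the planted change classes.

    Base isoforms of non-NTR loci receive 1-4 domains; each novel isoform's
    domain set is constructed so that comparing it with its base isoform
    reproduces the planted class exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0

    def add(tid: str, dom_ids: Sequence[str]) -> None:
        for k, d in enumerate(dom_ids):
            start = 10 + 60 * k
            rows.append(
                {
                    "transcript_id": tid,
                    "domain_id": d,
                    "aa_start": start,
                    "aa_end": start + 50,
                }
            )

    for locus in loci:
        if locus.gene_id in truth.ntr_loci:
            continue
        base = locus.transcripts[0]
        sib_classes = [
            truth.planted_domain_changes.get(t.transcript_id)
            for t in locus.transcripts[1:]
        ]
        n_dom = int(rng.integers(1, 5))
        if "some_lost" in sib_classes:
            n_dom = max(n_dom, 2)
        dom_ids = [f"DOM{counter + k:05d}" for k in range(n_dom)]
        counter += n_dom
        add(base.transcript_id, dom_ids)
        for t, cls in zip(locus.transcripts[1:], sib_classes):
            if cls == "all_retained":
                add(t.transcript_id, dom_ids)
            elif cls == "some_lost":
                n_drop = int(rng.integers(1, n_dom))
                keep = list(dom_ids[: n_dom - n_drop])
                add(t.transcript_id, keep)
            elif cls == "all_lost":
                pass
            elif cls == "gained":
                extra = f"DOM{counter:05d}"
                counter += 1
                add(t.transcript_id, list(dom_ids) + [extra])
    return pd.DataFrame(
        rows, columns=["transcript_id", "domain_id", "aa_start", "aa_end"]
    )


def make_last_exon_cohort(
    n_exons: int = 200,
    n_planted: int = 30,
    seed: int = 0,
    length_range: tuple[int, int] = (600, 2000),
    fpkm_range: tuple[float, float] = (4.0, 50.0),
    p_null: float = 0.5,
    p_planted: tuple[float, float] = (0.5, 0.75),
) -> tuple[list[GeneLocus], TruthSet, ExpressionTable]:
    """A cohort of single-exon transcripts for last-exon shift recovery.

    ``n_planted`` exons get the planted 3'-half proportion shift; the rest
    stay at ``p_null`` in both conditions.  FPKM is drawn uniformly from
    ``fpkm_range`` per condition so the expression filter and the log weight
    are both exercised.
    """
    if n_planted > n_exons:
        raise ValueError("n_planted cannot exceed n_exons")
    rng = np.random.default_rng(seed)
    planted_idx = set(
        int(i) for i in rng.choice(n_exons, size=n_planted, replace=False)
    )
    loci = []
    truth = TruthSet()
    expr = {}
    pos = 10_000
    for i in range(n_exons):
        gid = f"le{i:05d}"
        tid = f"{gid}.t0"
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        exon = GenomicInterval("chrQ", pos, pos + length, strand)
        pos = exon.end + 2000
        loci.append(GeneLocus(gid, (TranscriptModel(tid, gid, (exon,)),)))
        if i in planted_idx:
            truth.extended_hosts[tid] = p_planted
            truth.planted_extended_last_exons[exon_id(exon)] = p_planted
        else:
            truth.extended_hosts[tid] = (p_null, p_null)
        expr[tid] = (
            float(rng.uniform(*fpkm_range)),
            float(rng.uniform(*fpkm_range)),
        )
    return loci, truth, ExpressionTable(expr)
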