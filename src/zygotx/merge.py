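"""Merge alignment sets from two aligners so each read appears exactly once.

Short-read studies of this era commonly mapped with two aligners and merged
the results; the merge must leave every read id with a single best record.
"Best" is the deterministic preference order: more matched bases, then fewer
mismatches, then fewer blocks, then the lexicographically smaller aligner
tag, with block coordinates as the final tie-break.  A read multi-mapped
within one input is first reduced to its best record by the same order.
"""

from __future__ import annotations

from typing import Iterable

from .model import AlignedRead


def _preference_key(r: AlignedRead) -> tuple:
    return (
        -r.matched_bases,
        r.mismatches,
        len(r.blocks),
        r.aligner_tag,
        r.chrom,
        tuple((b.start, b.end) for b in r.blocks),
    )


def best_alignment(records: Iterable[AlignedRead]) -> AlignedRead:
    """The preferred record among alignments of a single read."""
    return min(records, key=_preference_key)


def _reduce(reads: Iterable[AlignedRead]) -> dict[str, AlignedRead]:
    best: dict[str, AlignedRead] = {}
    for r in reads:
        cur = best.get(r.read_id)
        if cur is None or _preference_key(r) < _preference_key(cur):
            best[r.read_id] = r
    return best


def merge_alignments(
    reads_a: Iterable[AlignedRead], reads_b: Iterable[AlignedRead]
) -> list[AlignedRead]:
    """One best record per read id across both inputs.

    Reads unique to one input pass through; a read present in both keeps
    the record preferred by :func:`best_alignment`.  Output is sorted by
    (chrom, start, read_id).
    """
    best = _reduce(reads_a)
    for rid, r in _reduce(reads_b).items():
        cur = best.get(rid)
        if cur is None or _preference_key(r) < _preference_key(cur):
            best[rid] = r
    return sorted(best.values(), key=lambda r: (r.chrom, r.start, r.read_id))
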