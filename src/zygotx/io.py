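"""Readers and writers for the plain-text formats the pipeline exchanges.

GTF lines are parsed with :mod:`gffutils` (Ensembl-style attributes) and
converted from 1-based inclusive to the internal 0-based half-open
convention.  BED stays 0-based half-open.  All writers emit deterministic
ordering (chrom, start, id) so identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .model import (
    AlignedRead,
    ExpressionTable,
    GeneLocus,
    GenomicInterval,
    Peak,
    TranscriptModel,
)


class GtfParseError(ValueError):
    """Raised for a malformed GTF line, naming the offending line number."""


def read_gtf(path: str | os.PathLike) -> list[GeneLocus]:
    """Read an exon-level GTF into gene loci.

    Only ``exon`` features are used; transcripts are grouped into loci by
    their ``gene_id`` attribute (the annotation's locus definition is taken
    as authoritative, no re-clustering by overlap).
    """
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    order: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - reported with line number
                raise GtfParseError(f"line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise GtfParseError(
                    f"line {lineno}: missing transcript_id/gene_id attribute"
                ) from exc
            if feat.start > feat.end:
                raise GtfParseError(
                    f"line {lineno}: exon start {feat.start} > end {feat.end}"
                )
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            key = (gid, tid)
            exons.setdefault(key, []).append(iv)
            order.setdefault(key, lineno)

    by_gene: dict[str, list[TranscriptModel]] = {}
    for (gid, tid), ivs in exons.items():
        tx = TranscriptModel(tid, gid, tuple(sorted(ivs)))
        by_gene.setdefault(gid, []).append(tx)
    loci = []
    for gid, txs in by_gene.items():
        txs.sort(key=lambda t: (t.span.start, t.transcript_id))
        loci.append(GeneLocus(gid, tuple(txs)))
    loci.sort(key=lambda l: (l.chrom, l.span.start, l.gene_id))
    return loci


def write_gtf(loci: Sequence[GeneLocus], path: str | os.PathLike) -> None:
    """Write loci as 1-based inclusive GTF with deterministic ordering."""
    lines = ["##provider: zygotx"]
    for locus in sorted(loci, key=lambda l: (l.chrom, l.span.start, l.gene_id)):
        for tx in sorted(
            locus.transcripts, key=lambda t: (t.span.start, t.transcript_id)
        ):
            for i, e in enumerate(tx.exons, start=1):
                attrs = (
                    f'gene_id "{locus.gene_id}"; '
                    f'transcript_id "{tx.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                lines.append(
                    "\t".join(
                        [
                            e.chrom,
                            "zygotx",
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_ALN_COLUMNS = [
    "read_id",
    "chrom",
    "strand",
    "blocks",
    "aligner_tag",
    "matched_bases",
    "mismatches",
]


def _format_blocks(read: AlignedRead) -> str:
    return ",".join(f"{b.start}-{b.end}" for b in read.blocks)


def write_alignments(reads: Iterable[AlignedRead], path: str | os.PathLike) -> None:
    rows = sorted(reads, key=lambda r: (r.chrom, r.start, r.read_id))
    with open(path, "w") as fh:
        fh.write("\t".join(_ALN_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        r.chrom,
                        r.strand,
                        _format_blocks(r),
                        r.aligner_tag,
                        str(r.matched_bases),
                        str(r.mismatches),
                    ]
                )
                + "\n"
            )


def read_alignments(path: str | os.PathLike) -> list[AlignedRead]:
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ALN_COLUMNS:
            raise ValueError(f"unexpected alignment header in {path}: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_ALN_COLUMNS):
                raise ValueError(f"line {lineno}: expected {len(_ALN_COLUMNS)} fields")
            rid, chrom, strand, blocks_s, tag, matched, mm = fields
            blocks = tuple(
                GenomicInterval(chrom, int(p.split("-")[0]), int(p.split("-")[1]), strand)
                for p in blocks_s.split(",")
            )
            reads.append(AlignedRead(rid, blocks, tag, int(matched), int(mm)))
    return reads


def write_peaks_bed(peaks: Iterable[Peak], path: str | os.PathLike) -> None:
    rows = sorted(
        peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    )
    with open(path, "w") as fh:
        for p in rows:
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.mark,
                        f"{p.score:g}",
                        p.interval.strand,
                    ]
                )
                + "\n"
            )


def read_peaks_bed(path: str | os.PathLike, mark: str | None = None) -> list[Peak]:
    """Read BED6 peaks; ``mark`` overrides the name column when given."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else (mark or "peak")
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            peaks.append(
                Peak(mark or name, GenomicInterval(chrom, start, end, strand), score)
            )
    return peaks


def write_expression_tsv(table: ExpressionTable, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(tid, pre, post) for tid, (pre, post) in table.items()],
        columns=["transcript_id", "fpkm_pre", "fpkm_post"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_tsv(path: str | os.PathLike) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "fpkm_pre", "fpkm_post"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return ExpressionTable(
        {
            str(row.transcript_id): (float(row.fpkm_pre), float(row.fpkm_post))
            for row in df.itertuples()
        }
    )


def read_domains_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "domain_id", "aa_start", "aa_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


def write_domains_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.sort_values(["transcript_id", "domain_id", "aa_start"]).to_csv(
        path, sep="\t", index=False
    )


def domain_sets(df: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Collapse a domain coordinate table to per-transcript domain-id sets."""
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.transcript_id), set()).add(str(row.domain_id))
    return {tid: frozenset(ids) for tid, ids in out.items()}


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(seqs.items())
    ]
    SeqIO.write(records, str(path), "fasta")
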