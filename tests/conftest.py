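import pytest

from zygotx.model import GeneLocus, GenomicInterval, TranscriptModel


def make_tx(coords, tid="t1", gid="g1", chrom="chr1", strand="+"):
    return TranscriptModel.from_exon_coords(tid, gid, chrom, strand, coords)


def make_locus(*transcript_coords, gid="g1", chrom="chr1", strand="+"):
    txs = tuple(
        make_tx(coords, tid=f"{gid}.t{i}", gid=gid, chrom=chrom, strand=strand)
        for i, coords in enumerate(transcript_coords)
    )
    return GeneLocus(gid, txs)


@pytest.fixture
def three_exon_locus():
    """Base transcript plus a sibling skipping the middle exon."""
    return make_locus(
        [(100, 200), (300, 400), (500, 600)],
        [(100, 200), (500, 600)],
    )


def mirror_locus(locus, axis=1_000_000):
    """Reflect a locus around ``axis`` and flip the strand (same molecule,
    written in the reverse genomic orientation)."""
    flip = {"+": "-", "-": "+"}
    txs = []
    for t in locus.transcripts:
        coords = [(axis - e.end, axis - e.start) for e in t.exons]
        txs.append(
            TranscriptModel.from_exon_coords(
                t.transcript_id, t.gene_id, t.chrom, flip[t.strand], coords
            )
        )
    return GeneLocus(locus.gene_id, tuple(txs))


def flip_strand(locus):
    """Same exon chains relabelled to the opposite strand (donor and
    acceptor roles swap)."""
    flip = {"+": "-", "-": "+"}
    txs = tuple(
        TranscriptModel.from_exon_coords(
            t.transcript_id,
            t.gene_id,
            t.chrom,
            flip[t.strand],
            [(e.start, e.end) for e in t.exons],
        )
        for t in locus.transcripts
    )
    return GeneLocus(locus.gene_id, txs)
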