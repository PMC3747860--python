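"""ORF prediction on transcript sequences and protein-domain comparison.

ORF calling scans the three forward reading frames only (transcript
sequences are already oriented 5'->3') for AUG..stop open reading frames and
reports the longest one above a minimum protein length, breaking length ties
towards the 5'-most start.  Domain comparison works on domain-identity sets:
a domain that is present but shifted still counts as retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .model import TranscriptModel

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID = frozenset("ACGT")

IN_FRAME = "in_frame"
FRAMESHIFT = "frameshift"

DOMAINS_ALL_RETAINED = "all_retained"
DOMAINS_SOME_LOST = "some_lost"
DOMAINS_ALL_LOST = "all_lost"
DOMAINS_GAINED = "gained"
DOMAIN_CLASSES = (
    DOMAINS_ALL_RETAINED,
    DOMAINS_SOME_LOST,
    DOMAINS_ALL_LOST,
    DOMAINS_GAINED,
)


@dataclass(frozen=True)
class OrfPrediction:
    """Longest predicted ORF, in transcript (spliced) coordinates.

    ``end_offset`` is exclusive and includes the stop codon, so
    ``protein_length = (end_offset - start_offset) / 3 - 1``.
    """

    transcript_id: str
    start_offset: int
    end_offset: int

    def __post_init__(self) -> None:
        span = self.end_offset - self.start_offset
        if span < 6 or span % 3:
            raise ValueError(
                f"{self.transcript_id}: ORF span {span} not a codon multiple >=6"
            )

    @property
    def protein_length(self) -> int:
        return (self.end_offset - self.start_offset) // 3 - 1

    @property
    def cds_length(self) -> int:
        return self.end_offset - self.start_offset


@dataclass(frozen=True)
class DomainChange:
    transcript_id: str
    reference_id: str
    change_class: str


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def find_longest_orf(
    seq: str, min_aa: int = 50, transcript_id: str = ""
) -> Optional[OrfPrediction]:
    """Longest forward-frame AUG->stop ORF with protein length > ``min_aa``.

    Only ORFs terminated by a stop codon inside the sequence qualify.  Ties
    in protein length resolve to the 5'-most start.  Returns None when no
    qualifying ORF exists.
    """
    s = _normalize(seq)
    best: tuple[int, int] | None = None  # (-protein_len, start)
    best_orf: tuple[int, int] | None = None
    for frame in range(3):
        open_start = -1
        for pos in range(frame, len(s) - 2, 3):
            codon = s[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_start >= 0:
                    plen = (pos + 3 - open_start) // 3 - 1
                    if plen > min_aa:
                        cand = (-plen, open_start)
                        if best is None or cand < best:
                            best = cand
                            best_orf = (open_start, pos + 3)
                    open_start = -1
            elif codon == START_CODON and open_start < 0:
                open_start = pos
    if best_orf is None:
        return None
    return OrfPrediction(transcript_id, best_orf[0], best_orf[1])


def find_longest_orf_naive(
    seq: str, min_aa: int = 50, transcript_id: str = ""
) -> Optional[OrfPrediction]:
    """Brute-force reference: enumerate every AUG..stop span in all three
    forward frames and pick by the same (length, 5'-most) rule."""
    s = _normalize(seq)
    candidates = []
    for start in range(len(s) - 2):
        if s[start : start + 3] != START_CODON:
            continue
        for pos in range(start + 3, len(s) - 2, 3):
            if s[pos : pos + 3] in STOP_CODONS:
                plen = (pos + 3 - start) // 3 - 1
                if plen > min_aa:
                    candidates.append((-plen, start, pos + 3))
                break
    if not candidates:
        return None
    _, start, end = min(candidates)
    return OrfPrediction(transcript_id, start, end)


def compare_cds(
    novel_tx: TranscriptModel,
    novel_orf: OrfPrediction,
    annotated_tx: TranscriptModel,
    annotated_orf: OrfPrediction,
) -> tuple[int, int]:
    """CDS and UTR length differences (novel minus annotated), in nt."""
    if novel_orf is None or annotated_orf is None:
        raise ValueError("both transcripts need a predicted ORF")
    cds_diff = novel_orf.cds_length - annotated_orf.cds_length
    utr_novel = novel_tx.length - novel_orf.cds_length
    utr_annot = annotated_tx.length - annotated_orf.cds_length
    return cds_diff, utr_novel - utr_annot


def classify_domain_change(
    novel_domains: Iterable[str],
    annotated_domains: Iterable[str],
    gained_precedence: bool = True,
) -> str:
    """Compare two domain-identity sets.

    ``gained`` wins whenever the novel isoform carries a domain absent from
    the annotated one (it is the small, interesting subgroup); with
    ``gained_precedence=False`` a mixed gain/loss is reported by its loss
    side instead.  Two empty sets are vacuously ``all_retained``.
    """
    novel = frozenset(novel_domains)
    annotated = frozenset(annotated_domains)
    gained = bool(novel - annotated)
    if gained and (gained_precedence or novel >= annotated):
        return DOMAINS_GAINED
    if novel == annotated:
        return DOMAINS_ALL_RETAINED
    if not novel:
        return DOMAINS_ALL_LOST
    return DOMAINS_SOME_LOST


def frame_impact(length_change_nt: int) -> str:
    """Reading-frame consequence of a splice-driven length change."""
    return IN_FRAME if length_change_nt % 3 == 0 else FRAMESHIFT
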