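# Methods

`zygotx` compares two bulk transcriptome states of an early embryo — before
and after zygotic genome activation (ZGA), i.e. maternal versus zygotic — at
the level of transcript structure. It takes assembled transcript models
(GTF), per-transcript expression in the two conditions (FPKM), spliced read
alignments, histone-mark peak calls, transcript sequences and a
protein-domain table, and produces: a transcript catalogue classified
against a reference, TSS/TTS diversity per locus, alternative-splicing (AS)
events with junction-read support, a ranked list of 3'-terminal exons whose
coverage lengthens after activation, and peak–exon association statistics.
Everything is testable offline because a synthetic-data generator plants all
of these structures with known coordinates.

## Coordinates and data model

Internal coordinates are 0-based half-open; GTF I/O converts to 1-based
inclusive at the file boundary and BED stays 0-based half-open, so there is
exactly one conversion site. Transcripts are strand-aware exon chains;
introns, TSS and TTS are derived, never stored. Loci are taken from
`gene_id` attributes (the annotation's locus definition), not re-clustered
by overlap. Peaks may be unstranded; transcripts must be stranded because
TSS/TTS are otherwise undefined.

## Aligner merge

Short-read data of the era were mapped with two aligners and merged. The
merge keeps each read id exactly once, preferring more matched bases, then
fewer mismatches, then fewer blocks, then the lexicographically smaller
aligner tag, with block coordinates as a final tie-break. This order is a
declared convention — it favours fuller, cleaner alignments and makes the
merge deterministic — not a reconstruction of any particular tool's rule.

## Transcript catalogue

A query transcript is **identical** to the reference when some same-strand,
exon-overlapping reference transcript has exactly the same intron chain
(terminal exon ends are free, so assembly end-truncation does not
manufacture novelty — the conventional "=" class-code semantics); a
**new_isoform** when it shares ≥ 1 exonic base on the same strand but no
intron chain; an **NTR** (novel transcribed region) otherwise. The closest
reference is the one sharing the most exonic bases (ties to the smaller
id). Expression filtering keeps transcripts with `max(FPKM_pre, FPKM_post)
> 3` (strict), i.e. robust expression in at least one condition; maternal
transcripts expressed only pre-activation survive.

TSS (and, with the same algorithm, TTS) diversity per locus is
single-linkage clustering of transcript 5' (3') ends. On a line this is:
sort the unique coordinates and cut where the gap exceeds the threshold.
The default threshold is 50 bp — nearby starts that short-read data cannot
distinguish are grouped — and 0 reproduces exact-identity counting; the
parameter is exposed because the right grouping radius depends on library
protocol. The cluster representative is the coordinate used by most
transcripts, ties to the most upstream.

Isoform-usage shifts are scored as the Jensen–Shannon distance (sqrt of the
JSD, base-2 logs) between the two conditions' isoform relative-abundance
vectors: 0 for proportional compositions, 1 for a complete switch. This is
descriptive plumbing, not a significance test.

## Alternative-splicing events

Events are extracted pairwise within a locus and deduplicated. For a
transcript pair, only the genomic region where both have aligned structure
(span intersection) is considered. A *shared splice site* is a position
that is an exon/intron boundary of the same kind in both transcripts; every
maximal stretch between two consecutive shared sites where the internal
structures differ is one variation unit, typed as:

* **ES** — one transcript splices straight across ≥ 1 complete internal
  exon(s) of the other (`n_skipped_exons` recorded);
* **IR** — an intron of one transcript lies inside an exon of the other;
* **AD** / **AA** — the strand-aware donor / acceptor boundary of a shared
  intron is shifted by ≥ 1 nt.

Units matching several patterns take the fixed precedence ES > IR > AD >
AA, so each unit gets exactly one type. Variation at transcript termini
(alternative first/last exons, TSS/TTS shifts) is deliberately not emitted:
those are isoform-structure differences handled by the catalogue and the
last-exon stage, and a terminal retained intron has no bounding shared site
and is likewise excluded. Pairwise-then-deduplicate was chosen over a full
splicing-graph traversal because it matches per-event counting granularity
and admits an exhaustive, mechanically independent reference implementation
(`extract_events_naive`, a per-base mask scanner) used to validate the
interval algebra on thousands of random loci.

Junction support for an ES event counts reads containing a block gap whose
boundaries *exactly* equal the skip junction (the donor end of the upstream
flank and the acceptor start of the downstream flank). No tolerance: splice
junctions are base-precise, and fuzzy matching would double-count
neighbouring acceptors.

## Last-exon lengthening (Q statistic)

A non-redundant database of strand-aware 3'-terminal exons is built
(duplicate coordinates collapse; contributors listed), filtered to length
> 400 bp and FPKM > 3 in *both* conditions (max over contributing
transcripts per condition). Each exon splits at `start + floor(length/2)`;
reads go to the half containing the midpoint of their overlap with the exon
(unambiguous for boundary-straddling reads). With `p = n_last / (n_first +
n_last)` per condition,

    Q = (p2 − p1) · ln((FPKM_pre + FPKM_post) / 2)

Reads shifting into the 3' half after activation give positive Q, weighted
by log mean expression so well-covered exons outrank noisy ones. `p` is the
bounded proportion rather than a last/first ratio: it stays finite when a
half is empty and keeps the sign interpretation. The natural log is used;
the base only rescales Q and never reorders exons, and the expression
filter guarantees the weight is positive. Exons with zero reads in either
condition are unscorable and excluded. Selection keeps Q > 0 (configurable)
sorted by descending Q, ties by total reads then coordinates, so the
ranking is independent of input order. How many exons truly lengthen is a
property of the data, not a constant of the method.

## Epigenome association

*Peak-to-TSS assignment* links a peak to every gene with a TSS within ±500
bp of the peak interval (0 if inside). *Bidirectional promoters* are
divergent opposite-strand gene pairs whose TSSs each lie within 1,000 bp of
a promoter-mark peak midpoint (floor on even lengths, for determinism),
with the minus-strand TSS at or left of the plus-strand TSS so each
transcript points away from the other; expression across pairs is
summarized by a Pearson correlation on gene-level FPKM (sum over
transcripts).

*Overlap enrichment* asks whether target exons (e.g. skipped exons)
co-localize with peaks beyond chance. Each exon is extended to its event
region — upstream intron start to downstream intron end — and counts as
overlapped at ≥ 1 shared bp with any peak. The null draws `|targets|` exons
uniformly **without replacement** from the exon universe, independently per
iteration (default 1,000), with an explicit seed. Reported together:
`empirical_p = (1 + #draws ≥ observed) / (1 + iterations)` and a 2×2
Pearson chi-square (overlapped vs not × observed set vs pooled null draws,
1 df, no continuity correction). Both are emitted because a bootstrap mean
and a chi-square answer subtly different questions; reporting both keeps
the inference auditable.

*Metagenes.* Coverage metagenes rescale each exon to 100 bins 5'→3' and
divide per-bin mean coverage by reads-per-million. ChIP metagenes use
intron–exon–intron triplets (50 bins per segment) with per-bin signal
`(ChIP RPM + 0.5) / (input RPM + 0.5)`; the 0.5 pseudocount guards
zero-coverage input bins, and the RPM ratio makes the profile invariant to
uniform down-sampling. A null band (2.5th/97.5th percentile per bin) comes
from random placements of size-matched triplets over the covered
chromosomes.

## Synthetic data: what it emulates and what it does not

`generate_annotation` lays loci along four chromosomes with generous
margins, 3–8 exons (120–400 bp) and introns of 200–1,500 bp; isoform count
per locus defaults to {1: 0.25, 2: 0.50, 3: 0.25} (≈ 2 isoforms per
multi-isoform locus, the regime these analyses target). Each extra isoform
differs from the base by exactly one modification — single/double cassette
exon, donor or acceptor shift of 6–60 nt, retained internal intron, or a
distinct first/last exon — on non-adjacent exons, so the planted events are
exactly the variation units a pairwise extractor must find. A 10% fraction
of loci is withheld from the reference to plant NTRs; planted domain-change
classes default to proportions dominated by full retention with a small
"gained" subgroup. Planted last-exon extensions shift the 3'-half read
proportion 0.50 → 0.75 on exons of 600–2,000 bp.

`simulate_reads` places 50-nt reads uniformly over each transcript's
spliced length (length × abundance weighting within a skip pair, so the
planted inclusion/skip fraction is what junction-spanning reads report in
expectation), maps them through the exon chain, and tags each read id with
its source transcript — which makes FPKM derivation and junction tallies
exact bookkeeping rather than estimation. `simulate_peaks` covers
planted-associated exons with a given probability and adds uniform Poisson
background (for the enrichment experiments the background is 0.145
peaks/kb, chosen so a typical ~2 kb event region has ≈ 30% baseline overlap
with 500 bp peaks).

The generator deliberately omits: sequencing errors and quality scores,
positional coverage bias, multi-mapping ambiguity, incomplete or fragmented
assemblies, overlapping genes, and expression estimation noise (FPKM is
derived from true read counts). Passing recovery tests therefore
demonstrates the *algorithms* are correct under their stated definitions —
not that the pipeline is robust to assembler artefacts or biased coverage
in real libraries.

## Validation experiment sizes

The recovery experiments (in `zygotx.evaluation`, reused by the test suite
and `scripts/acceptance.py`) run at: 1,000 loci for the event-extraction
cross-check; 300 loci at depth 50 for exact truth recovery; 40 loci at
depth 2,000 for junction-fraction calibration; 20 replicate cohorts of 200
last exons (30 planted) at 200 reads/exon/condition for Q-score recovery;
200 null datasets and 100 planted datasets (100 targets, 2,000-exon
universe, 999 bootstrap iterations) for enrichment calibration and power;
500 random sequences up to 3,000 nt for the ORF cross-check; and 100,000
uniform reads for metagene flatness. These sizes give comfortable
statistical resolution for each property while keeping a full run in the
order of a minute.

## Known limitations

* Event extraction is pairwise; a locus whose variation only appears when
  three transcripts are compared jointly (e.g. nested complex units) is
  reported as the union of pairwise units.
* "Identical" classification ignores sequence content; CDS comparison is
  length-based, and amino-acid-level identity is not implemented.
* The Q statistic detects within-exon coverage shifts only; switching to a
  different (longer) terminal exon is a catalogue-level isoform change, not
  a Q hit.
* The chi-square on pooled null draws treats draws as independent samples;
  the empirical bootstrap p-value is the primary statistic.
* The merge step models single-end reads; pairing logic and SAM flag
  semantics are out of scope.
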