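# Methods

This note records the models implemented in `aluexon`, the parameter choices
that matter, the design decisions taken where the design was genuinely open,
and the limits of what the synthetic data can demonstrate.

## Coordinate and data model

All coordinates are 1-based and inclusive on both ends (`length = end −
start + 1`), the convention of GTF and SAM; BED input is converted at the
boundary and pysam's 0-based in-memory positions are converted inside the SAM
reader.  Every module consumes the domain types of `aluexon.io`
(`GenomicInterval`, `TranscriptModel`, `AluAnnotation`,
`ReadAlignmentRecord`); no module re-parses files.  *Alu* subfamily names map
to age classes by prefix (AluJ/AluS/AluY); names beginning `Alu` without an
age letter fall into a generic bucket.

## Fixed-element arm

Candidate exons come from assembled transcript models, one set per sample.
The three filters — internal exon, *Alu* antisense to the transcript strand,
strict length bounds 40 < L < 400 bp — are applied per sample and the
surviving exons merged across samples by exact coordinates.  Decisions:

* **Length bounds are strict** (40 and 400 excluded); both bounds are
  configurable.
* **"Internal"** means at least one exon on each side within the same
  transcript model.
* **Known vs novel** requires exact coordinate identity with an annotated
  exon — the only reproducible rule; near-matches stay novel.
* **One locus, many exons**: distinct exon coordinates over the same *Alu*
  are separate rows of a single locus, so locus counts and exon counts
  differ by design.
* **Intron-support rescue**: a sample counts as supporting an exon when both
  flanking introns (taken from the call's transcript context) have at least
  `min_reads` (default 1) spliced alignments in that sample.  The reporting
  threshold for the "robust" subset defaults to support in ≥ 2 samples.

## Splicing and PSI

Only *simple* cassette events are considered: an inclusion isoform
(…, A, E, B, …) and a skipping isoform (…, A, B, …) with flanks A and B
coordinate-identical in both.  Junction counting is exact-boundary: a spliced
alignment supports an intron iff one of its CIGAR N-gaps covers exactly that
span; near-miss junctions are not merged.  Per sample,

    PSI = (L + R) / (L + R + 2 S)

over the two inclusion junctions (L, R) and the skipping junction (S).  The
factor 2 compensates for the skipping isoform presenting one junction where
the inclusion isoform presents two.  PSI is undefined below 10 total
supporting reads (per sample, per event).  The cohort summary is the median
of defined per-sample values (mean behind a flag).  Categories: minor
(PSI < 0.35), equal ([0.35, 0.65)), major (≥ 0.65); the lower bound of
"equal" closes the otherwise-unassigned band [0.35, 0.36).

## Tissue specificity

From an intron × sample count matrix with a sample → tissue map:

* **Presence**: an intron is present in a tissue when ≥ 15 % of that
  tissue's samples have ≥ 10 reads (both thresholds inclusive and
  configurable).
* **Absence**: per tissue, the expected number of absent samples is
  E_t = 0.85 · N_t (kept fractional) and the observed O_t is the number of
  samples under the read threshold.  Columns with O_t < E_t are dropped —
  absence there is within the sampling margin — and the retained columns are
  tested with the goodness-of-fit statistic Σ (O−E)²/E on k−1 degrees of
  freedom.  Fewer than two retained columns returns p = 1.  A 2 × n
  independence variant (absent/expressed per tissue) exists behind a flag;
  it is degenerate (p = 1) for introns absent everywhere outside the target
  tissue and is not the default.
* **Call**: tissue specific iff present in exactly the target tissue and
  absence p ≤ 0.001 (comparison inclusive).

A property worth knowing: a fully absent tissue contributes only
(0.15 N)² / (0.85 N) ≈ 0.0265 N to the statistic, so rejecting at
p ≤ 0.001 requires repository-scale cohorts — with four tissues, roughly 175
samples per tissue.  Small cohorts cannot produce tissue-specific calls under
this construction; the synthetic matrices therefore use 200 samples per
tissue.  No multiple-testing correction is applied by default.

## Read classification

Reads are classified as *Alu*-derived with an exact canonical k-mer index
(k = 31, the standard exact-classification length) over a library of the
*Alu* consensus plus all annotated genomic copies.  A read is an *Alu* read
when ≥ 10 % of its k-mers hit the index; the low threshold keeps chimeric
exon–*Alu* mates — which may carry only a few tens of *Alu* bases —
classifiable.  Classification is reverse-complement invariant and monotone in
the library.  Reads whose *Alu* stretch is shorter than k contribute no
*Alu* k-mer at all and are invisible to the classifier; this bounds the arm's
sensitivity for junction-hugging mates and is intrinsic to exact k-mer
matching.

## Alignment engine

A single affine-gap Smith–Waterman (match +1, mismatch −1, gap open −2
charged on the first gap base, extend −0.5) serves all alignment needs.  For
the signal test the target is *segmented* — anchor exon, consensus, adjacent
exon — and the DP may jump at zero cost from any position of one segment to
any position of a later segment, which is exactly a splice across the
segment boundary.  With one segment the engine reduces to plain local
alignment, used by the shadow test and contig prioritization.  Identity is
matches / aligned columns (gap columns count); query coverage is the spanned
query fraction.  The DP is JIT-compiled with numba; the test suite pins it
against an independently written full-matrix oracle and against Biopython's
`PairwiseAligner` on single-segment instances.

Signal evaluation tries both read orientations, both consensus orientations
and both flank concatenations (anchor→Alu→next, prev→Alu→anchor), passing if
any configuration passes — an unmapped mate's sequencing orientation and the
insertion side are unknown a priori.  The shadow "unspliced" windows are
taken on both sides of the anchor exon (500 bp each); the "region" target
spans from the anchor exon to the farther of its two neighboring annotated
exons.

## Vicinities, context filter, insertion intervals

Category partition per mate: S (signal ∧ ¬shadow), SRU (signal ∧ shadow),
RU (shadow only), none; SN counts S ∪ none.  Within a gene, anchors chain
into vicinities by single-linkage ≥ 1 bp overlap; clusters within a vicinity
are additionally separated by anchor orientation and category, and a read
anchored to several exons of one gene counts once.  The five filter
conditions use the calibrated defaults (2, 5, 0, 2, 0.5); ratios with a zero
denominator pass their condition (absence of shadows is the strongest
evidence, consistent with the default MIN_S2SN = 0).  Per signal cluster the
insertion interval runs to the nearest opposing-orientation cluster in the
direction the anchors face, falling back to the gene boundary, and is
clipped to the gene span.  A call is flagged repeat-rich when > 50 % of its
interval is covered by annotated repeats (threshold configurable).  Base-pair
precise breakpoints are out of scope: the interrupted structure of mRNA
fundamentally limits localization to an interval.

## Assembly and contig prioritization

The bundled assembler is a deliberately simple de Bruijn walker (k = 23,
odd): contigs are maximal non-branching paths after one round of tip
clipping (dead-end branches ≤ 2k hanging off a junction); bubbles are kept so
haplotypes surface as separate contigs.  Reads are used in the orientation
given — reverse-complement read pairs can yield mirrored contigs, which
prioritization handles by aligning both strands.  Any external assembler can
be substituted upstream of `prioritize_contigs`, which flags contigs lacking
a ≥ 90 % identity, ≥ 80 % coverage local match to the gene region.

## Calibration

`excise_alus` deletes *Alu* spans from the genome and shifts all downstream
annotation coordinates by the cumulative deleted length (excision of copies
overlapping annotated exons is refused); the excision plan supports exact
forward and inverse coordinate mapping, and lifted exons are base-identical
to their originals.  Random selection of elements draws with replacement and
deduplicates, so n draws yield somewhat fewer unique elements.  The filter
grid — MIN_SIGNALS {1,2}, MIN_SIGNALNONE {1..10}, MIN_S2SN {0..0.5 by 0.1},
MIN_S2SRU {0..2 by 0.5}, MIN_S2RU {0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.5};
4,200 tuples — is evaluated by re-filtering precomputed vicinity count
tables, so alignment happens once.  Metrics are gene-level: Sn = TP/gold,
Pr = TP/reported, F = 2SnPr/(Sn+Pr) with 0/0 → 0, Acc = (Sn+Pr)/2; ranking
is by F, ties by Pr then Sn.  Genes with several insertions are one gold
unit.

## Synthetic data

The generator lays genes head-to-tail on one chromosome: 4–7 exons of
120–260 bp, introns of 800–1,400 bp, one antisense *Alu* copy per gene
placed 120 bp into an intron — close enough to its exon that pre-mRNA
fragments produce anchored shadow reads, and inside the 500 bp unspliced
window.  Intronic copies are mutated from the consensus at 10 % (aged,
AluS-like); planted non-reference inserts at 2 % (young, AluY-like) — the
two divergences are what make signal and shadow reads separable at the 93 %
shadow identity threshold, as in real data.  Reads are 100 bp pairs from
~N(300, 30²) fragments at 30× per isoform with 0.5 % base error and a 10 %
pre-mRNA share.  The generator itself plays the mapper: mates overlapping a
planted insert are emitted unmapped (their sequence is not in the genome),
pre-mRNA mates with ≥ 25 bp inside an *Alu* copy are emitted unmapped as
multi-mapping discards, and everything else gets a correct spliced CIGAR.
Five chimeric signal pairs per insertion are emitted deterministically with
55–75 *Alu* bases in the unmapped mate, pinning the study condition "five
signal pairs per event" independent of coverage sampling.  A fixed seed
makes all outputs byte-identical.

Not emulated: mapping ambiguity beyond the two discard rules above, base
quality, indel sequencing errors, expression heterogeneity, RNA editing, and
genomic repeat families other than *Alu*.  Passing tests therefore
demonstrate the logic of the pipeline under clean alignment semantics, not
robustness to aligner-specific artifacts.

The calibration driver plants non-reference inserts directly rather than
excising after the fact: a fixed exonization followed by excision of its
element is observationally identical to a planted insertion, so the two
constructions are interchangeable and the excision operator is verified
separately by its sequence-identity property.

## Numerical and degenerate-input conventions

PSI of all-zero counts is undefined regardless of the read cutoff.  The
absence test returns p = 1 with fewer than two retained tissues.  Context
ratios with zero denominators pass.  The aligner returns an empty result
(score 0) when nothing scores positively.  Assembly of reads all shorter
than k returns no contigs with a warning.  Excision targets overlapping each
other are an error; targets overlapping exons are skipped with a warning.
Chromosome-edge shadow windows are truncated, not errors.

## Problem sizes

Default study conditions are 20 genes with 5 planted insertions (about
120 kb of genome and ~4,000 read pairs) for the insertion arm, 12 genes with
6 planted exonizations for the fixed arm, and 45 introns × 800 samples for
the tissue matrix; the full calibration grid re-scores 4,200 tuples from one
analysis pass.  These sizes exercise every code path while keeping a full
run in seconds on one CPU.
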