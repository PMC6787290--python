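# Methods

## Coordinates and isoform identity

All internal coordinates are 0-based half-open; 1-based formats (GTF,
SAM) are converted at the I/O boundary only, so no off-by-one arithmetic
lives in analysis code. A transcript's structural identity is its intron
chain — (chromosome, strand, ordered intron boundary list) — so isoforms
match across samples regardless of terminal-exon end variation, which
long reads measure noisily. Mono-exonic transcripts, having no introns,
are identified by their exact exon bounds instead. The TSS is the
5′-most transcribed base: the first exon's start on the plus strand, the
last exon's final base on the minus strand.

SAM query intervals are reconstructed from soft *and* hard clips (hard
clips count toward read length), and flipped for reverse-strand records
so that all segments of one read live on the original read's coordinate
system — the property fusion detection depends on. Mapping-quality-0
segments are kept by default and can be dropped (`keep_mapq0=False`).

## Novelty classification

A query is a known isoform when its intron chain equals an annotated
transcript's. Otherwise it is a novel isoform of the annotated gene with
which it has maximal same-strand exonic overlap (≥1 bp; intron-only
containment deliberately does not count — it is the conservative overlap
notion). Remaining queries are clustered into novel loci by
single-linkage same-strand exonic overlap; the locus representative
(longest exonic length, ties to the lexicographically smaller id, which
makes the outcome order-independent) and any transcript sharing its
chain are "isoform of a novel gene", structurally distinct ones "novel
isoform of a novel gene". Queries whose only annotation overlap is
antisense go to the novel-gene classes with an `antisense` flag so the
information is preserved rather than forced into either category.

TSS-to-peak distance is unsigned: 0 inside a peak, else the gap to the
nearest peak boundary on the same chromosome. Transcripts on peak-less
chromosomes carry an infinity sentinel and are excluded from the
within-*d* summary fractions.

## Splicing events and divergence

Events are derived from all ordered transcript pairs of a gene and
deduplicated by (type, defining coordinates), the way local-event
enumerators report unique events. Definitions: SE — an internal exon
whose two flanking introns' outer boundaries form one skipping intron of
the partner; RI — an intron whose flanking exon boundaries bound a
single merged exon of the partner; MXE — two mutually exclusive internal
exons sharing both outer flanking boundaries; A5/A3 — intron pairs
sharing one boundary whose differing splice sites sit on *overlapping*
exons (assigned 5′/3′ strand-aware); AF/AL — differing non-overlapping
terminal exons spliced to a shared boundary. The overlap requirement on
A5/A3 and the terminal-exon requirement on AF/AL prevent the spurious
splice-site calls that a naive shared-boundary rule would emit for every
skipped exon.

The divergence score of gene j is D_j = Σ_i (1 − c_i/d_i) with
c_i = |a_i ∩ b| and d_i = |a_i ∪ b|, where b is the normal sample's
isoform-key set and a_i cancer sample i's. A comparison where the gene
is absent from both samples contributes 0 — absence in both is no
divergence, and this keeps D defined without a 0/0. The number of terms
generalizes from the study design's fixed 4 to the number of cancer
samples, which is also D's upper bound. Event-type proportions are
compared with a χ² test on the raw count table, no continuity
correction, df = (r−1)(c−1); all-zero event-type columns are dropped
(they carry no information and break the expected-count denominator).

## lncRNA stage

The consensus filter keeps a transcript only when all four predictors
call it noncoding; a missing predictor is an error, not an implicit
"noncoding". lincRNA means no span overlap with any protein-coding gene
span on either strand. The cancer-specific set is
(∪ cancer sets) ∖ (normal ∪ reference catalog); the union reading of
"detected in the cancer cells" is the default, with an intersection mode
available, because presence in any cancer sample suffices for the set
sizes such studies report. "Not expressed in the normal sample" is
interpreted as absence from the supplied presence set — thresholding
happens upstream of this package.

Target calling requires Pearson r > 0.95 with two-sided p < 0.001 (the
t-transform with n−2 df) and a span-to-span gap below 100 kb. Note the
two thresholds are jointly unsatisfiable at n = 5 samples (r = 0.95,
df = 3 gives p ≈ 0.013), so the synthetic validation uses 12 expression
samples, where r > 0.95 implies p ≈ 10⁻⁶; both thresholds remain
independently configurable. Zero-variance vectors are skipped with a
warning rather than propagating an undefined r.

The pre-miRNA search aligns each hairpin (and implicitly both strands,
via the lincRNA's reverse complement) with a local aligner scoring
match +1, mismatch −2, gap −2.5; a hit needs ≥90% identity over ≥90% of
the hairpin length. These thresholds are this package's defaults — the
upstream protocol only says "blast" — and are exposed as parameters.

## Fusion detection

The four criteria are conjunctive and evaluated independently, so the
per-read audit reports every violated criterion, and filter order cannot
change the result. Combined coverage uses the *union* of query intervals
(overlapping segments are not double-counted, otherwise heavily
overlapping alignments could fake full coverage). Locus separation is
the gap between genomic intervals' closest edges; different chromosomes
always satisfy it; for reads with more than two loci every pair must be
separated and every locus must meet the 10% fraction. Junction support
from raw short reads defines "spanning" as ≥8 bp aligned on both sides
of the breakpoint and counts flanking reads in a 100 bp window on each
side — both values are conventions of this package, not of the upstream
protocol, and are parameters. When a precomputed (s, a, b) table is
supplied it is passed through verbatim. Tier-2 ("a/s < 2 and b/s < 2")
is read as a selection of comparably expressed fusions for verification;
s = 0 fails it by definition rather than dividing. Database matching is
on the unordered gene pair after symbol-to-stable-id mapping; records
with unmapped symbols are skipped and reported.

## Synthetic data

The generator mirrors the emulated study's design: 5 samples (one
normal-like, four cancer), ~100 coding genes laid out without overlap,
150 kb apart so neighbouring genes are separable under the 100 kb fusion
rule, two genes planted per splicing-event type as a two-transcript pair
differing by exactly that event, and 200 long reads — 20 true fusions,
5 reads per failure class each violating exactly its one criterion, and
160 ordinary reads. lincRNA loci sit on a dedicated chromosome with
partner coding genes at 40 kb (close) or 150 kb (beyond-window) gaps and
500 kb between clusters, so the only lincRNA-gene pairs inside the
window are the planted ones and the close decoys. Expression is a shared
log-normal latent profile with multiplicative log-normal jitter
(σ = 0.25) for correlated pairs, rejection-sampled until the realized r
clears the 0.95 threshold; close decoys are rejection-sampled to
|r| < 0.8; the expression matrix has 12 samples (see the p-value note
above). All generators are pure functions of the configuration; the seed
is mandatory and every derived stream offsets it deterministically.

What the generator does *not* emulate: sequencing error profiles,
quality scores, genome sequence content, expression covariance structure
beyond the planted pairs, or multi-isoform genes with more than one
simultaneous event. Passing the recovery tests therefore shows the
detectors implement their rules exactly, not that the rules are robust
to real-data noise such as ambiguous alignments or borderline coverage.

## Problem sizes and numerical choices

The validation suite and the acceptance script run the generators at
their defaults (127 genes, 200 reads, 12 expression samples, 10,000
permutations for the p-value cross-check), which completes in seconds
while exercising every rule and failure class. FLNC/CCS ratios round
half-even to two decimals with trailing-zero trimming for display
("0.8"), which reproduces the published five-cell-line QC column from
its printed counts. Ties in gene ranking break lexicographically;
report assembly is deterministic (timestamp only on request).

## Known limitations

- Novel-locus subcategories ("isoform of a novel gene" vs "novel isoform
  of a novel gene") follow a representative-vs-additional rule that is
  one reasonable reading of the category scheme; the clustering is
  single-linkage and a different linkage would shift locus boundaries.
- Event enumeration is pairwise-local; it does not build a splice graph,
  so combinatorial events spanning three or more transcripts are
  reported as their pairwise projections.
- The fusion junction's genomic breakpoint is taken from alignment
  segment edges; no breakpoint assembly or realignment is attempted.
- Coding-potential predictors are consumed as call tables; running them
  is out of scope, as is any external-database enrichment.
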