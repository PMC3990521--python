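# Methods

`occupeak` implements the downstream statistics of a comparative ChIP-seq
occupancy study: two peak sets called from two experiments (here labelled A
and B) are compared at the signal level, annotated against genes and
chromatin states, associated with a sequence motif, and linked to
differentially expressed genes.  Everything runs on a seeded synthetic
study so each stage's answer can be scored against planted truth.

## Coordinate conventions

All coordinates are 0-based half-open (BED convention); refFlat `txStart`
is already 0-based and is taken as-is.  A peak's *center* is
`floor((start+end)/2)` and anchors every center-based assignment (category,
chromatin state, TSS distance, binary overlap); the called summit is kept
on the `Peak` record but deliberately unused, since the assignment rules
are defined on peak centers.  Readers validate every record against the
declared chromosome layout; out-of-bounds records are errors, never
clipped.

## Unique/common classification

For each peak of one experiment, reads are counted in a 200 bp window
centred on the peak center in *both* signal tracks, regardless of whether
the other experiment called a peak there.  The peak is *unique* when

* the rpm ratio (own / other) is at least the fold threshold (default 4),
  with the other experiment's rpm floored at the equivalent of half a read
  so an empty window cannot produce an infinite fold; and
* an exact conditional binomial test rejects equal rpm at `alpha`
  (default 1e-4).

The test conditions on `n = count_A + count_B`; under the null of equal
reads-per-million, `count_A ~ Binomial(n, lib_A/(lib_A+lib_B))`.  The
two-sided p doubles the smaller tail and caps at 1, which is conservative
(the acceptance suite verifies empirical `P(p <= 0.05) <= 0.06` under an
equal-intensity Poisson null).  `n = 0` returns p = 1: no reads, no
evidence.  Unique + common = total by construction.

## Functional categories

Seven labels partition the genome: promoter (1 kb upstream of the TSS,
strand-aware), TTS (1 kb downstream of the termination site), 5'UTR, 3'UTR,
coding exon, intron, intergenic (the remainder).  UTRs are strand-aware and
exon-restricted.  Overlaps between features of different transcripts are
resolved by the fixed precedence `promoter > tts > utr5 > utr3 > exon >
intron`; the explicitly windowed small classes must not be swallowed by
introns of neighbouring genes.  Two implementations coexist on purpose —
a per-base painted array (for genome background fractions) and a sorted
interval query (for peak centers) — and tests assert they agree base by
base on toy genomes.

Per-category enrichment of a peak set uses the exact one-sided binomial
tail against the genomic background fraction, tested in the direction of
the observed deviation.  Two peak sets are compared per category under a
pooled null: with totals `m, n`, category counts `m', n'` and combined
frequency `f = (m'+n')/(m+n)`, the statistic is the product of the two
one-sided binomial tails of `(m, m')` and `(n, n')` at `f`, each taken on
the side of that set's deviation from `f`, capped at 1.  The side choice
follows the observed deviation because the comparison is reported
per-category in whichever direction the sets differ.

TSS-distance histograms count each peak once at its signed distance to the
*nearest* TSS (negative = upstream, strand-aware), in 500 bp bins;
nearest-TSS rather than all-TSS counting avoids multi-counting peaks in
gene-dense regions.  Equidistant ties resolve to the lower-coordinate TSS.

## Chromatin states

A 15-label segmentation (chromHMM-style dense BED) must tile each
chromosome exactly; label bp fractions therefore sum to 1.  Peaks are
assigned to the state containing their center (half-open segments, so a
center on a boundary belongs to the following segment).  "% coverage" for
peaks is the fraction of peak centers, consistent with center-based
assignment.  One-sided binomial p-values take the direction of the
deviation, so depleted states are tested on the "less" side.  Named groups
(e.g. the two promoter states, the four enhancer states) pool member counts
and genome fractions exactly.  A "top" subset keeps peaks with rpm
strictly above 1.

## Motif association

IUPAC patterns expand to explicit {A,C,G,T} character classes, so `N` in
the subject sequence never matches.  Scanning reports overlapping matches
on the forward strand plus reverse-complement matches mapped to forward
coordinates, deduplicated per (chrom, start); the TPA-response element
TGASTCA (S = G or C) is its own reverse complement under degeneracy, so
its hit set is strand-closed.  A peak is motif-positive when at least one
match lies fully inside the peak interval (flank 0 by default: the
association is defined on the called peak itself, no window extension).
Association of motif-positive peaks with a peak subset uses the upper-tail
hypergeometric test against the full peak population.

Binary cross-experiment overlap declares peaks from two sets common when
their centers lie within 100 bp (center distance, not padded-interval
intersection; a peak pairing several partners counts once in its own set's
common count).

## Expression linkage

A peak links to a gene when its interval intersects the gene body extended
1 kb upstream of the TSS (the same promoter window as the category layer,
for internal consistency).  Gene-list summaries report: occupied genes (%
of listed genes, integer), distinct linked binding sites (% of all peaks,
one decimal), and motif-bearing linked sites (% of linked sites) — the
percentages' denominators follow the published table layout this mirrors.
Significance of the binding-site count comes from a Monte-Carlo null that
re-places the same number of peaks, widths preserved, uniformly on the
genome (chromosome chosen proportional to length; no GC or mappability
matching) and reports `z = (obs - mean)/sd` with a normal upper-tail p.
The empirical rank p `(1 + #{null >= obs})/(n_reps + 1)` is reported
alongside; note it is tie-conservative for a discrete count statistic, so
calibration checks of uniformity apply to the normal-tail p.  A constant
statistic (sd = 0) is an error, not a silent zero.

## qPCR arithmetic

Relative expression uses the classic `2^-ddCt` form with amplification
efficiency fixed at 2 per cycle: target Ct normalized to a reference gene,
sample normalized to a control condition.  MNase-protection enrichment is
`2^-(Ct_chromatin - Ct_naked)` per replicate pair, normalized to naked
genomic DNA, summarized as mean +/- SEM; SEM is reported as missing with
fewer than two replicates.

## The synthetic study

The generator emulates the *downstream products* of a two-experiment study
— peak tables with rpm, per-base read-start tracks, gene annotation,
chromatin segmentation, genome sequence, DE gene lists — not raw reads or
peak calling.  Defaults (one choice, fixed):

* genome: 2 chromosomes x 500 kb, i.i.d. bases at GC 0.41.  1 Mb keeps
  every stage fast while leaving room for ~160 well-separated peak loci.
* genes: 60 non-overlapping transcripts of 2–6 kb, 1–5 exons, CDS bounds
  on exonic sequence, random strand.  This puts ~24% of the genome inside
  transcript spans, in line with mammalian gene density, and leaves enough
  unoccupied genes to build gene lists with controlled overlap.
* segmentation: 15 labels with fibroblast-like target fractions
  (heterochromatin ~65%, promoter/enhancer states ~5%), exponential
  segment lengths (mean 1 kb) and quota-proportional label draws so
  realized coverage lands within 2% of target at 1 Mb.
* peaks: 120 in A, 80 in B, width 200 bp, frac_shared 0.5 (so 40 common
  loci, 80/40 unique).  Unique loci exist in *both* tracks at expected
  intensity ratio `unique_fold` = 8 — uniqueness in the classification
  sense is an intensity ratio, not absence.  Reads are Poisson
  (mean 200 per peak, library-size-proportional) deposited uniformly
  within the peak, over a 20k-read uniform background per track.
  With these rates a planted unique locus shows a realized ratio >= 4
  with probability > 0.95, so the 4-fold/alpha classifier can be scored
  meaningfully.
* motifs: TGASTCA planted at the center of 40% of peak loci.  Peak
  intervals are scrubbed of *chance* motif occurrences (either strand)
  before planting, so motif flags are recoverable exactly; background
  sequence outside peaks keeps its chance occurrences.
* gene lists: two lists of 20 in which 35% of members overlap peaks (body
  or 1 kb promoter); disjoint when the occupied/unoccupied pools allow.

Every stage draws from `default_rng([seed, stage_tag])`, so each product is
independently reproducible under the config seed, and the truth table
(locus label, expected intensities, motif flag, per-set peak index) is
sufficient to score classification, motif recovery and linkage exactly.

What the generator does **not** model: fragment-length effects, GC or
mappability bias, read-level noise, overlapping genes, non-coding
transcripts, peak-width variation, correlated replicates.  Passing
truth-recovery tests therefore demonstrates that the statistics recover
the structure they are designed for at realistic densities — not that they
are robust to every artefact of real libraries.

## Numerical choices

* Percentages render half-up at the target precision (35.99% -> 36%).
* Exact tails come from scipy's binomial/hypergeometric distributions;
  tests cross-check them against explicit pmf summation and urn
  enumeration at small n.
* Degenerate inputs fail loudly: empty peak sets, background fractions of
  0 or 1, sd-zero Monte-Carlo nulls, unresolvable gene-list ids (reported,
  never dropped silently).
* Problem sizes in the test-suite simulations (1 Mb genomes, 100–10,000
  replicates) are chosen so every statistical check has the power it
  needs while the whole suite stays interactive.

## Known limitations

* Printed fold values in the published chromatin-state table cannot be
  recovered exactly from the rounded printed percentages (they were
  evidently computed on unrounded values); state folds here are computed
  from unrounded fractions and compared only structurally.
* The genome-scale results of the original study (17,779 peaks on hg19)
  require the deposited raw data; this package reproduces the printed
  percentage arithmetic and validates the statistical machinery on
  synthetic data instead.
* The between-set category comparison's side choice at exact equality
  (`m'/m == f`) takes the "greater" tail; both tails are >= 0.5 there, so
  the product is insensitive to the choice.
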