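# Methods

## Evidence model

The caller consumes coordinate-sorted paired-end alignments (SAM/BAM). A read
pair contributes junction evidence when

1. one read maps uniquely and contiguously — operationalized as a single-match
   CIGAR with total clipping < 5 bp and mapping quality ≥ 20 (both
   configurable; "unique" is not quantified further than the MAPQ threshold);
2. the other read is a split read: a primary alignment carrying an `SA`
   descriptor of its supplementary placement, both placements on the same
   strand. Split reads whose two placements are on opposite strands would
   imply an inverted junction; these are counted into a side channel and never
   called (the model covers simple, non-inverted circles).

Secondary alignments are always discarded. Supplementary records without a
reachable primary are skipped and counted. Duplicate-flagged pairs are kept by
default so every junction remains discoverable; they are excluded from the
quantitative support count (`n_split_support` = distinct non-duplicate read
ids per junction, `n_evidence_reads` = all evidence items including
duplicates — both are reported).

Coordinates are 0-based half-open internally; human-readable labels
(`GENE^circle 50,447,497–50,447,834`) are 1-based inclusive.

## Direct-repeat junction correction

A junction joining reference position *e* (circle end, exclusive) back to *s*
(circle start) is ambiguous when the sequences entering both breakpoints
match: if `genome[s:s+k] == genome[e:e+k]` the aligner may place the split
boundary at any of k+1 offsets. The correction shifts the junction leftward
while `genome[s-1] == genome[e-1]` holds (window capped at 100 bp, truncated
at chromosome edges) and records the total equivalence-window size. The shift
is a function of the genome only — deliberately not limited by how the
particular read was split — so every legal offset of one physical junction
canonicalizes to identical coordinates, the operation is idempotent, and
support groups exactly. The leftmost offset is the canonical one, matching
common aligner left-normalization; reported direct-repeat lengths come from an
independent rescan of the canonical coordinates.

## Single-fragment calls

Corrected same-chromosome evidence is grouped by exact (chrom, start, end).
A group becomes a call when the placements are head-to-tail on one strand
(second split segment strictly left of the first segment's end) and the
anchored mate overlaps the circle interval — any overlap, not containment,
because after rolling-circle amplification a mate may itself straddle the
junction. The default support threshold is 1 split read; the analyses this
package mirrors report all junctions, and the threshold is configurable for
stringency. Cross-chromosomal evidence is routed to the multi-fragment path,
never dropped.

## Multi-fragment circles

Confident regions are intervals whose start and end coincide with corrected
cross-chromosomal breakpoints and whose every base has read coverage ≥ 1.
Coverage is computed from all mapped records; because raw alignments may place
a split boundary anywhere inside a junction direct repeat, the canonicalized
placements of the junction reads are overlaid on the raw coverage before the
100% check — the repeat-adjacent bases are physically covered by those reads
under the canonical representation, and without the overlay fragments with
long planted repeats are spuriously rejected. Regions longer than 100 kb
(configurable) are rejected with a logged reason.

Regions are nodes of a directed graph with an edge U→V for each observed
junction (U.chrom, U.end) → (V.chrom, V.start). Simple cycles of length 2 or
3 visiting pairwise distinct chromosomes are reported in canonical rotation
(lexicographically smallest fragment first), each adjacency annotated with its
distinct-read support. Cycles sharing a region are all reported and flagged;
cycles longer than 3 are returned separately, never merged into the main call
set.

## Size, repeat and end-base profiles

Sizes are end − start. Modal sizes are local maxima of the 1-bp histogram
after Gaussian-kernel smoothing, ranked by smoothed height. The default
bandwidth is 16 bp: nucleosome-ladder modes sit ~150 bp apart, and at a few
thousand calls a 16-bp kernel localizes each mode to within ~2 bp, whereas
narrow moving-average windows (5–30 bp boxes) track the Poisson noise of
individual bins and misplace the mode by 5–10 bp. Quantiles use the
order-statistic convention `quantile(q) = sorted_sizes[floor(q·n)]`, i.e. the
boundary below which a fraction q of molecules are shorter; the median is
`quantile(0.5)`.

The direct-repeat finder returns the largest k ≤ 20 (configurable) with
`genome[start:start+k] == genome[end:end+k]`, exact matches only, truncated at
chromosome edges. End-nucleotide composition reads the final circle base
(forward reference strand, 1-based position `end`) by default; the convention
is configurable to the start base since the defining end is not standardized.
Default size classes are < 2,000, 2,000–3,000 and > 3,000 bp.

## Genome distribution and element enrichment

Calls are binned by start breakpoint into non-overlapping 1-Mb bins (trailing
partial bins kept) and normalized to fractions. Two call sets are compared
with a two-sample KS test on the per-call bin indices reconstructed from the
counts — identical distributions give D = 0 and disjoint single-bin masses
give D = 1; applying KS to the count vectors themselves would compare the
multisets of bin densities instead and cannot distinguish those cases.

Junction loci are both breakpoints of each call (configurable to start-only).
Classification is multi-label: a locus receives every class containing it
(promoters = 2 kb upstream of genes, strand-aware; immediate downstream = 2 kb
downstream; CpG-island flanks = 2 kb either side; distal intergenic = the
complement of all genic/CpG/derived tracks). The enrichment score divides the
class's share of junction loci by its share of the genome, so every class has
expected score 1 under uniform placement; classes with zero merged coverage
are excluded with a warning.

## Enhancer overlap of joined regions

Per sample, the observed score is the fraction of unique multi-chromosomal
joined regions intersecting ≥ 1 enhancer, divided by the enhancers' merged
genome fraction (each region counts once however many enhancers it hits). The
null replaces the regions with length-matched random regions — chromosome
drawn proportional to length among chromosomes the region fits, start uniform
over legal positions, fully seeded — and summarizes n_draws = 20 draws by
their mean (n_draws = 1 reproduces a single-draw null). Observed vs null pairs
across samples are tested with the exact one-tailed Wilcoxon signed-rank
test; with fewer than ~5 samples the minimal attainable p (2^-n) is reported
alongside.

## Exact rank tests

Signed-rank and rank-sum p-values are exact for up to 25 observations:
mid-ranks are doubled to integers and the null distribution of the statistic
is built with the distribution-counting recurrence (equivalent to enumerating
all 2^n sign assignments / C(n, m) group assignments over the observed tie
structure). Two-sided p is 2·min(tail p) capped at 1. Beyond n = 25 a normal
approximation with continuity correction (and tie-corrected variance for the
rank-sum) is used. All-zero differences yield p = 1 with a degenerate flag.
The KS test uses the asymptotic two-sample distribution.

## Abundance, recurrence, biomarkers

A gene accrues the split-read support of every call overlapping its body (a
call overlapping k genes counts toward all k; an optional ±2 kb extension is
off by default). Normalized abundance is counts per million total split reads
per sample; the exported count matrix is raw integers because downstream
count-based differential tools apply their own normalization. Recurrent
("highly abundant") circles are identities present in ≥ 2 samples of a group;
identity is exact (chrom, start, end) by default, with an optional
single-linkage tolerance whose clusters are flagged when wider than twice the
tolerance. Biomarker candidates are set intersections of per-group recurrent
gene sets with per-direction differential gene sets. Breakpoint-flank FASTA
records are 150 bp — 50 bp inside the circle plus 100 bp outside at each
breakpoint, with the inside/outside orientation configurable in code — and
records clipped by a chromosome edge are dropped and counted, never silently
truncated.

## Simulator

The simulator is first-class, tested code that defines the study conditions
for every validation:

- **Genome**: random ACGT chromosomes (≥ 50 kb) with internally consistent
  gene (exon/intron/UTR, both strands), CpG-island, labelled-repeat and
  enhancer tracks; one seed makes all FASTA/GTF/BED outputs byte-identical.
- **Truth circles**: single-fragment sizes from the bimodal mixture
  N(201, 15) / N(348, 20) in equal weight (the nucleosome-ladder modes of
  circle-seq libraries); two- and three-fragment circles place each fragment
  on a distinct chromosome. Junction direct repeats are planted by editing
  the genome so each junction carries an exact k-bp repeat, with flanking
  bases adjusted so the homology is exactly k (otherwise chance matches would
  shift the canonical junction off the planted truth). k is 0 with
  probability 0.6, else uniform on 1–10 bp, giving ~36% of circles a ≥ 2 bp
  repeat — inside the 32–42% band reported for real placenta/plasma
  libraries.
- **Reads**: 150-bp pairs from Normal(250, 25) fragments. RCA chemistry draws
  fragments from a tandem concatemer of the circle (geometric copy number,
  mean 5 — amplification depth is not published, so it is a free, configurable
  parameter); tagmentation draws fragments directly on the circle.
  Junction-spanning reads are emitted bwa-mem-style as a soft-clipped primary
  plus supplementary with mutual `SA` tags and MAPQ 60; the split boundary of
  a junction with a k-bp repeat is drawn uniformly among the k+1 legal
  offsets, reproducing exactly the ambiguity the correction step must undo.
  `depth` is the mean number of junction-spanning pairs per circle
  (Poisson-distributed); non-junction pairs drawn along the way are also
  emitted, which supplies the body coverage the confident-region check needs.
  A configurable fraction of pairs is duplicate-flagged (default 0 — real
  duplicate rates are not published). Reads wrapping a circle more than once
  (or spanning two junctions of a three-fragment circle) emit the first
  junction only and soft-clip the rest; later wraps are lost by design.
- **Not modelled**: base qualities, indel errors, GC bias, chimeric
  artifacts, mitochondrial circles, real genome coordinates. Substitution
  errors default to 0 (the pipeline operates post-alignment, and error
  modelling is orthogonal to every property tested). Passing tests therefore
  demonstrate the correctness of the calling logic on faithful split-read
  representations, not robustness to alignment noise in real libraries.

Reads are written as already-aligned SAM (the simulator knows the truth
placement), which removes any aligner dependency while preserving the
caller's exact input contract; a FASTQ export exists for integration against
a real aligner.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use 500 single-fragment circles
(depth 30) for recall/precision, 50 two- + 20 three-fragment circles for
assembly, 60 repeat-planted circles with all legal offsets enumerated for
canonicalization, 1,000 random breakpoints for the repeat-finder oracle,
5,000 uniform calls × 50–100 seeds for enrichment calibration, 20 replicate
5-sample experiments for the enhancer-null type-I check, and n = 2,000 size
mixtures for mode detection. These sizes give binomial/Monte-Carlo margins
comfortably inside the asserted tolerances while keeping a full run fast on a
single CPU.

## Known limitations

- Inversion circles and deletion-like splits are excluded by design.
- A confident region pairs each start breakpoint with the nearest downstream
  end breakpoint; heavily nested cross-chromosomal junction clusters on one
  chromosome could be mis-paired.
- "100% genomic coverage" counts all reads, not only reads assignable to the
  region's circle.
- The KS comparison of genome distributions treats bins as ordered categories
  via bin indices; alternative conventions exist and the choice matters for
  power, not validity.
- Whether supportive split-read counts should include duplicates is
  ambiguous in the field; both counts are carried, deduplicated support is
  the default everywhere quantitative.
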