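# Methods

This note records the models, conventions and numerical choices behind
`nucmeth`, in the order data flows through the package.

## Coordinates and containers

All internal coordinates are 0-based half-open; 1-based conversion happens
only in `nucmeth.io` behind explicit flags. Interval lists live in
`IntervalSet` (a sorted DataFrame of chrom/start/end/strand/score/name);
midpoints in `MidpointTrack` (per-chromosome sorted int64 arrays); per-base
coverage in `CoverageTrack`. Read records carry the *strand-aware 5′
coordinate*: the leftmost aligned base for forward reads, the rightmost for
reverse reads. No operation mutates its inputs.

## Fragment-length estimation (strand cross-covariance)

Forward and reverse 5′-start depth vectors are mean-centered per chromosome
and cross-covariance is pooled over chromosomes for shifts 1..`max_offset`
(default 400 bp; the scan range is a free choice, set to comfortably bracket
mononucleosomal lengths). Because the reverse 5′ end sits on the *last*
fragment base, fragments of length L peak at shift L − 1; at bp resolution
either value is reported as the mean fragment length.

Peak location matters more than it looks: with broadly distributed fragment
lengths (sd ≈ 20 bp) the covariance curve is shallow near its maximum and the
raw argmax wanders several bp under shot noise. The estimator therefore
boxcar-smooths the curve (default 15 bp) and reports the centroid of the
contiguous above-half-maximum region around the smoothed argmax. For an
isolated covariance spike (discrete fragment lengths) the smoothed plateau is
centered on the spike, so the centroid is exact; for smooth peaks its
variance is far below the argmax's. `smooth=1` recovers the raw argmax.

## Deduplication, size filter, midpoints

- Duplicates are capped at **two copies** per (chrom, 5′ start, strand)
  locus, retention order stable. Strand is part of the key because
  opposite-strand reads at one coordinate are distinct fragments. The
  operation is idempotent.
- The pair-length filter keeps the central 95% of the empirical length
  distribution; bounds are the 2.5th/97.5th percentiles with linear
  interpolation between order statistics (the textbook definition, so a
  sort-and-slice oracle can reproduce the retained set exactly). Retention is
  inclusive at both bounds; an all-identical sample collapses the bounds and
  retains everything with a warning. At least 40 pairs are required —
  percentile estimates below that are not meaningful.
- Single-end midpoints use the **half-offset** convention: 5′ ± offset/2
  (integer-floored). Read literally, "start plus the offset" would place the
  point at the fragment's far end rather than its middle; since the offset
  estimates the mean fragment length, the half shift is what centers the
  point on the dyad, and recovery tests confirm it. The literal full-offset
  convention stays available via `halve_offset=False`.
- Paired midpoints are ⌊(leftmost + rightmost)/2⌋ per retained pair;
  cross-chromosome mates are dropped and counted.
- Coverage tracks extend each read 3′-ward to the mean fragment size
  (default 160 bp) and scale per-base counts by 10⁶/total reads; the track
  integral therefore equals extension × 10⁶ exactly.

## Site-anchored profiles

Anchors are strand-aware (a minus-strand feature anchors at `end − 1`) and
offsets are mirrored so transcription runs left-to-right. All anchored
windows are half-open [a, b) after mirroring — the BED convention, applied
uniformly so boundary behavior is predictable (a midpoint exactly at the
downstream edge is excluded). TSS metagene profiles pool counts over sites in
5 bp bins across ±1 kb and normalize per million midpoints; a per-site-mean
normalization is available behind a flag (pooled-sum is the default because
it weights sites by data rather than equalizing sparse ones). Promoter
occupancy counts midpoints in the strand-aware −500..+250 window.

Enrichment ratios divide per-bin counts pooled over sites by the expected
count under genome-uniform density (total midpoints / genome length × bin
width × site count), so ratio 1 is background. Expression classes exclude
zero-expression genes, then assign quartile and decile labels by rank after a
stable sort on (value, gene id) — ties are resolved deterministically.

Peak-set overlap calls a query peak overlapping when it shares at least 10%
of *its own* length with the (merged) reference set, inclusive at the
threshold; a reciprocal-overlap mode is available. Replicate reproducibility
is this fraction for every ordered pair of peak sets. Peak-to-TSS distance is
edge-to-point and inclusive at the 1 kb default.

## Windowed correlation

The genome is tiled into fixed 2 kb windows (final partial tile kept,
flagged). Per-window density is log₂((n_ChIP + pc)/(n_background + pc)) with
pseudocount pc = 1: log base 2 gives doubling units and the symmetric
pseudocount keeps empty windows finite; windows empty in both tracks are
excluded from correlations by default since the ratio carries no information
there. A midpoint belongs to exactly one tile. Pearson r and its two-sided
t-transform p come from scipy after pairwise dropping of missing values;
constant input raises rather than returning an undefined coefficient.

## Methylation-site classification

Strand calls are paired against the genome sequence: a plus-strand CpG
cytosine at p pairs with the minus-strand cytosine at p + 1, a CWG cytosine
at p with the minus-strand cytosine at p + 2 (the reverse complement of CWG
is again CWG). Calls whose declared context disagrees with the sequence are
dropped and counted; unpaired calls are returned separately so call counts
are conserved.

A strand counts as methylated at pct ≥ 50 (the per-strand threshold is not
part of the published rule set and is exposed as configuration). Sites with
both strands methylated are homomethylated, exactly one hemimethylated,
neither excluded. The level rule uses the **methylated-read mass**
Σ coverage × pct/100 over both strands, rounded half-up, because the same
mass formula drives the windowed methylated-read aggregation; high requires
strictly more than 10 reads, so a site with exactly 10 is moderate (the
published classes are defined by ">10" and "<10", leaving 10 unassigned; we
assign it to moderate and document the choice). Per-class enrichment profiles
are ranked by the mean ratio over the central ±250 bp; if the spread of
central ratios is below 0.1 the ordering is reported as not distinct
(uniform-background data should not yield a confident hierarchy).

## Differential methylation

β = M/(M + U) with missing (flagged) output at zero total intensity; the
Illumina offset of 100 in the denominator is *not* applied by default because
the analysis this package reimplements uses the offset-free formula. QC masks
probe×sample measures with detection p > 0.05 and removes samples whose
passing-probe fraction falls below 95% ("coverage" is taken as that fraction;
no other definition is available). The global shift test is the paired
Wilcoxon signed-rank: zeros dropped, midranks for ties, and the p-value exact
for up to 25 informative pairs via dynamic programming over the null
distribution of W⁺ (doubling midranks makes them integers; the distribution
is built by convolution); beyond 25 the scipy normal approximation without
continuity correction is used. All-zero differences return statistic 0,
p = 1.

Per-site classification: log₂ fold change of β with a 10⁻⁶ floor before the
ratio (β = 0 must not break the rule; the floor is configurable), hyper iff
fc > 1, hypo iff fc < −1, strict, so exact doubling is unchanged. The
classifier is antisymmetric under swapping treated/untreated.

CpG islands: every 200 bp sliding window with GC > 0.5 and observed/expected
CpG = N_CpG·L/(N_C·N_G) > 0.6 (dinucleotides counted fully inside the
window) qualifies; qualifying windows are unioned into maximal intervals.
Only the thresholds are published, not a procedure, so the sliding-window
union is *defined* to be correct by an exhaustive-scan oracle in the tests.
Island context by distance to the nearest island edge: 0 → island,
≤ 2000 → shore, ≤ 4000 → shelf, else open sea (boundaries inclusive).
Functional regions follow the precedence TSS200 > TSS1500 > 5′UTR > 1stExon >
gene body > 3′UTR; "gene body" is the transcript minus the gene's own
annotated UTR/first-exon features — otherwise the lower-precedence 3′UTR
could never be assigned. TSS200/TSS1500 are strand-aware upstream windows
excluding the TSS itself.

Category summaries report counts and percentages to two decimals
(round-half-up) with denominator equal to the reported total of differential
sites — passed explicitly when the per-axis counts and the reported total
disagree, as published count sets sometimes do. Gene sets partition genes
into hyper-only, hypo-only and both, with (region, class) pairs reported for
"both" genes.

## The synthetic-data generator

One `numpy` Generator per simulation, seeded explicitly; equal seeds give
byte-identical outputs, and every dataset ships with a truth table (dyad
positions, site classes, spiked probe ids) so recovery tests never infer
truth from the data.

- **Genomes** are i.i.d. nucleotides at a requested GC fraction (default
  0.41, the human genome-wide value). `make_site_genome` plants isolated
  CpG/CWG motifs at fixed spacing on an A/T background for enrichment
  experiments where neighboring sites must not share profile windows —
  random sequence at human GC has a methylation-context site every ~15 bp,
  which would blur per-class windows together.
- **Fragments**: centers at weighted dyads plus uniform jitter (default
  ±10 bp, emulating MNase trimming variability; no spacing model is imposed —
  spacing is whatever the dyad list says), lengths normal(150, 20) — the
  spread implied by a central-95% interval of ~90 bp — with a uniform
  background fraction (default 0.1). Mate 5′ ends sit at the first and last
  fragment bases.
- **Methylomes** emit both strand calls at every context site. Methylated
  strands report ~90% methylation, unmethylated ~5%, far from the 50%
  threshold so truth and derived labels agree; moderate-coverage sites are
  capped so their methylated-read mass stays at or below the 10-read
  boundary. Per-class binding multipliers (`methylation_effect`) default to
  a monotone ladder from hemi-CWG-moderate (3.2×) down to
  homo-CpG-high (1.1×).
- **Signal tracks** with target correlation ρ are ρ·z + √(1−ρ²)·e with the
  noise projected orthogonal to the standardized reference, so the sample r
  concentrates tightly around ρ; |ρ| = 1 returns an exact affine transform.
- **450K tables**: baseline β from an equal Beta(2,12)/Beta(12,2) mixture
  (modes near 0.1 and 0.9 — array methylation is strongly bimodal); spiked
  probes shift by ±dm_effect_size in log2 with candidates restricted so the
  shift stays inside (0, 1); replicate noise is Beta(βk, (1−β)k) with
  precision k = 2000, i.e. intensity-like noise that shrinks toward the
  extremes — additive Gaussian noise would manufacture spurious large log
  fold changes at small β.

What the generator does **not** model: sequencing error, mappability bias,
GC amplification bias, CpG depletion (real genomes are CpG-poor; random
sequence is not), probe cross-hybridization, or batch effects. Passing
recovery tests therefore demonstrates correctness of the estimators under
clean planted structure, not robustness to every artifact of real libraries.

## Problem sizes

Recovery experiments use sizes at which the statistics are decisive while
the whole suite stays fast: 50,000 fragments / 1,000 dyads for offset and
midpoint recovery, 10,000 lengths for the size filter, 5,000 × 2 kb windows
for correlation recovery, 10,000 spaced sites / 400,000 fragments for the
eight-class hierarchy, 10,000–12,000 probes for the differential-methylation
branch, 100 samples of n ≤ 12 for exact signed-rank enumeration, and 50 kb
sequences for the island-detector oracle.

## Known limitations

- The strand-offset estimator assumes a unimodal fragment-length
  distribution per library; strongly multimodal libraries return one of the
  modes (tested), not the mean.
- Enrichment ratios assume a globally uniform background; locally varying
  MNase accessibility would need the total-nucleosome normalization of the
  windowed branch instead.
- The 450K branch consumes per-probe β or intensities; raw chip processing
  (dye bias, within-array normalization, peak correction) is out of scope and
  β values flow through as given, with a logged notice.
- Exact signed-rank p-values are computed for up to 25 informative pairs;
  larger samples use the normal approximation, whose p can differ from the
  exact tail in the extreme far tail.
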