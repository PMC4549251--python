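# nucmeth

Nucleosome-resolution ChIP-seq analysis and its interplay with DNA
methylation, as a tested Python library with a synthetic-data generator for
every input it consumes.

## The problem

Chromatin factors such as PARP1 can be mapped at single-nucleosome resolution
by immunoprecipitating MNase-derived mononucleosomes and sequencing the
protected fragments (nuc-ChIP-seq). Interpreting such libraries requires a
chain of small but exacting steps: reducing read pairs to nucleosome
**midpoints** (dyads), anchoring those midpoints on genomic sites (TSSs, DHS,
CTCF, methylated cytosines), normalizing against a total-nucleosome
background, and correlating windowed signal with other chromatin tracks.
Because factor binding interacts with DNA methylation, the package also
carries a methylation branch: strand-resolved classification of CpG and CWG
(W = A/T) sites into homo-/hemimethylated and high/moderate coverage classes,
and an Infinium-450K-style differential-methylation analysis for
treatment/control comparisons.

`nucmeth` is a library: the importable API is the interface, with short
narrative scripts under `examples/` (one per capability).

## Methods at the core

- **Fragment-length estimation.** The mean nucleosomal fragment length is the
  shift *d* maximizing the cross-covariance between forward- and
  reverse-strand read-start depth, cov(f, r; d) = Σᵢ f̃ᵢ r̃ᵢ₊d; the peak is
  located as the half-max centroid of the smoothed covariance curve.
- **Midpoints.** Single-end: read 5′ coordinate ± d/2 (strand-aware). Paired:
  pairs outside the central 95% of the fragment-length distribution are
  discarded, then midpoint = ⌊(leftmost + rightmost)/2⌋.
- **Site-anchored profiles.** Midpoint counts in 5 bp windows over ±1 kb
  around stranded anchors (minus-strand anchors mirrored), normalized per
  million midpoints; enrichment ratios divide per-window density by the
  genome-wide mean density.
- **Windowed correlation.** 2 kb genome tiles; per-window density
  log₂((n_ChIP + 1)/(n_background + 1)); Pearson *r* with a two-sided *t* p.
- **Methylation classes.** A strand is methylated iff pct ≥ 50; both strands
  → homo, exactly one → hemi; methylated-read mass = Σ coverage·pct/100,
  high iff > 10 reads. Eight classes: {hemi, homo} × {CpG, CWG} × {1, 10}.
- **Differential methylation.** β = M/(M+U); probe×sample QC at detection
  p > 0.05 and 95% sample coverage; paired Wilcoxon signed-rank (exact by
  enumeration up to n = 25); a site is hyper/hypomethylated iff
  |log₂(β_t/β_u)| > 1 (strict); CpG islands are merged 200 bp windows with
  GC > 0.5 and observed/expected CpG > 0.6, with shore (≤ 2 kb), shelf
  (2–4 kb) and open-sea context by distance.

## Worked example

`python examples/04_methylation_hierarchy.py` plants nucleosome binding that
decreases across the eight methylation classes and recovers the ordering from
data:

```
10000 sites classified (5018 hemi, 4982 homo)
recovered binding hierarchy (central enrichment ratio over genome mean):
  hemi-CWG1      4.69
  hemi-CpG1      4.19
  hemi-CWG10     3.70
  hemi-CpG10     3.13
  homo-CWG1      2.73
  homo-CWG10     2.34
  homo-CpG1      2.06
  homo-CpG10     1.85
matches planted ordering: True
```

Each ratio is the midpoint density in the central ±250 bp of a 2 kb window
around sites of that class, divided by the genome-average density: > 1 means
enrichment over background, and the strict descent across classes recovers
the planted inverse relationship between binding and methylation
completeness. The other examples cover midpoint recovery (`01`),
expression-graded TSS profiles (`02`), windowed correlation (`03`) and
differential methylation (`05`).

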