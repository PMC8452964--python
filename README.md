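# pmdscape

Analysis toolkit for single-base maps of modified cytosines in heterogeneous
tumour cell populations: kernel-normalized 5hmC density tracks, partially
methylated domain (PMD) calling, methylome-based two-component cell-mixture
deconvolution, and the differential statistics that tie hydroxymethylation to
gene expression.

It is written for epigenomics analysts working with tagging-based sequencing
(TOP-seq-style) data, where reads are primed from covalently labelled
cytosines and read starts fall within a few nucleotides of the modified site.
The package consumes site-level read-start counts (bedGraph), genome layouts
(chrom.sizes + gaps BED), gene models (GTF) and interval annotations (BED),
and ships a fully ground-truthed synthetic-data generator so every stage can
be validated without external downloads.

## What it computes

**h-density.** Read starts are assigned to the nearest same-strand cytosine
0–3 nt downstream. For CpG sites the normalized density is

&nbsp;&nbsp;&nbsp;&nbsp;h(x) = f̂_w(x) / f̂_CG(x),

where f̂_w is an Epanechnikov-kernel density of CpG coverage (bandwidth
180 bp, read counts normalized to sum to 1 as weights, evaluated on a uniform
~120-bp grid and Gaussian-smoothed onto the CpG positions) and f̂_CG is the
unweighted CpG-site density (bandwidth 80 bp). The ratio cancels library size
exactly and removes local CpG-spacing bias.

**PMD calling.** The genome is tiled in 10-kb windows; a window qualifies
when ≥ 30% of its CpGs are identified unmethylated (uCG, ≥ 1 supporting read)
and it holds ≥ 5 CpGs. Qualifying windows closer than 10 kb are concatenated;
regions strictly larger than 10 kb that avoid assembly gaps form the PMD set.
Unique "2-cell-PMDs" between a pair of cell types are the non-overlapping
PMDs whose uCG fraction exceeds the 0.75 quantile of the partner's fractions
over the same regions; "4-cell-PMDs" are tiles covered by exactly one cell
type.

**Deconvolution.** To estimate the two daughter-cell-type proportions inside
a parental line, uCG identification status is swapped between the
daughterlines at a fraction f of CpG sites (f = 1–99%), and the concentration
of replicate-consistent uCG calls inside each cell type's unique 2-cell-PMDs
(relative to the motherline PMD set) is recorded as a calibration curve.
The parental sample's observed concentration is inverted through the curve by
piecewise-linear interpolation; the method is validated by recovering the
mixing proportion of true read-level mixtures.

**Differential statistics.** 1-kb regions pass a technical-reliability ANOVA
filter, then a fixed-effects linear model (cell type + condition + CpG
blocking) with Tukey HSD contrasts flags differentially hydroxymethylated
regions; genes are tested by a paired t-test over their CpG sites (BH within
gene-type stratum); differential expression uses an exact conditional
negative-binomial test at a fixed dispersion of 1e-4 after stratified
upper-quartile normalization and log2 RPKM; and a Gaussian linear model
quantifies how 5hmCH status, PMD localization and enhancer overlap predict
expression. Fisher/permutation enrichment and replication-timing quintile
grouping round out the integration layer.

## Worked example

`examples/01_simulate_and_call_pmds.py` builds a 5-Mb genome, plants PMDs
over ~30% of it (uCG 45% inside vs 12% outside), draws 3× uTOP-seq-style
reads and calls the domains back:

```
CpGs simulated:        51,383
reads drawn:           36,455 (0 unassigned)
planted PMDs:          8 covering 32% of the genome
called PMDs:           9
Jaccard(called,truth): 0.963
```

A Jaccard of 0.96 means the window caller reconstructs the planted domain
boundaries almost exactly from noisy single-read evidence.
`examples/03_deconvolve_mixture.py` then deconvolves true read-level mixtures
of two simulated cell types through the swap-calibration curve:

```
true p  |  estimated cell0 fraction
  0.25  |  0.298  (observed statistic 0.140)
  0.50  |  0.570  (observed statistic 0.194)
  0.75  |  0.776  (observed statistic 0.229)
```

The remaining examples cover the h-density gene profile (the 3'UTR class is
maximal when 5hmC is seeded at gene 3' ends), the differential test battery
on planted effects, and Fisher/permutation enrichment with replication-timing
groups. Each script runs in seconds and prints what its numbers mean.

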