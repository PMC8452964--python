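# Methods

This note records the models implemented in `pmdscape`, the defaults and the
reasoning behind the choices that were genuinely open.

## Coordinates and data containers

All internal coordinates are 0-based half-open; GTF (1-based closed) is
converted at the parsing boundary and back on write. Interval collections are
plain pandas DataFrames (`chrom`, `start`, `end` [, `strand`, `name`,
`score`]); cytosine site tables add `pos`, `strand` and the dinucleotide
context (CG/CA/CT/CC), with both strands of each palindromic CpG listed and
validated. Interval overlap is strand-blind unless explicitly requested
(needed only for the coding-strand 5hmCH analysis); promoters, downstream
regions and gene-relative positions are always strand-aware.

Derived annotations: CGI shores are the 2-kb regions flanking a CGI, shelves
the next 2 kb; where neighbouring CGIs collide, higher-priority features win
(CGI > shore > shelf) by interval subtraction. Promoter = 2 kb upstream of
the TSS; downstream = 2 kb past the TTS; both clipped at chromosome ends.

## Read assignment and site calling

A read start is assigned to the nearest same-strand cytosine 0–3 nt
downstream in read orientation (configurable window; ties cannot occur on one
strand, and the nearest-site rule is deterministic). Calling thresholds:
uCG and 5hmCG need one assigned read — windows "count uCGs irrespective of
coverage" — while 5hmCH needs two reads, reflecting the weaker evidence for
non-CpG marks. The false-positive rate under site-level Poisson noise ε is
then P(Pois(ε) ≥ 2), which the tests verify in closed form.

## h-density

Per chromosome, stage 1 evaluates a weighted Epanechnikov-kernel density
K(u) = 0.75(1 − u²)·1[|u| ≤ 1], u = distance/bandwidth, on a uniform grid;
per-CpG read counts normalized to sum to one within the sample are the
weights (bandwidth 180 bp). Stage 2 interpolates the grid onto the CpG
positions by Gaussian (Nadaraya–Watson) smoothing truncated at 5σ. The same
two stages without weights and with an 80-bp Epanechnikov bandwidth give the
CpG-site density; h-density is the ratio, with sites whose denominator
vanishes flagged non-finite and removed by the log2 floor (−30) before 50-bp
aggregation.

Two choices were open:

* **Grid resolution.** Full-size chromosomes would use a fixed point count
  (2^21); for arbitrary chromosome lengths the package
  fixes the grid *spacing* instead (default 120 bp ≈ 249 Mb / 2^21) so the
  kernels see the same resolution at any scale. The grid origin is
  configurable, which makes the track exactly translation-covariant.
* **Stage-2 bandwidth.** The smoothing bandwidth is shared between the two
  passes and defaults to the coverage bandwidth (σ = 180 bp). Using the
  narrower CpG bandwidth for the unweighted pass leaves coherent grid-phase
  ripple in the denominator: on a uniformly spaced, uniformly covered toy
  chromosome the interior coefficient of variation is 6.2% with stage-specific
  smoothing versus 1.3% with the shared bandwidth, and a ratio track should be
  flat there. `smoothing_sigma` exposes the alternative.

Because the weights are normalized, h-density is exactly invariant to global
count multiplication; smoothing also makes technical replicates of h-density
correlate better than the raw per-site counts, which the acceptance checks
measure rather than assume.

## PMD calling

10-kb non-overlapping windows advanced in 10-kb steps (a non-overlapping tiling
and a 10-kb-increment sliding window coincide under this reading; `width` and the merge gap are parameters).
A window qualifies with ≥ 30% identified uCGs among ≥ 5 CpGs; qualifying
windows with inter-window distance below 10 kb merge (adjacent tiles have
distance 0, tiles separated by one failed window have distance exactly 10 kb
and do not merge); regions strictly larger than 10 kb that do not overlap
assembly gaps survive. The strict inequality makes the size filter
meaningful: one isolated qualifying tile never becomes a PMD. The caller is
tested for exact interval equality against a brute-force
enumerate/merge/filter oracle on random landscapes, and lowering the uCG
threshold can only grow the called set.

For the 2-cell unique sets, "uCG signal above the 0.75 quantile of the other
cell line" is implemented as: candidates are PMDs with zero overlap with the
partner's PMDs, retained when their own region-level uCG fraction exceeds the
0.75 quantile of the partner's fractions over those same candidate regions —
the only uCG statistic the window table defines. PMD profiles use 20 equal
body windows regardless of domain size plus 10-kb-tiled 50-kb flanks.
Boundary analyses use 3-kb inner/outer edge windows (inner windows truncate
at the domain midpoint) with optional log-spaced distance bands.

Gene localization classes: Outside (no overlap), Inside (body fully within a
domain), Edge-Promoter (domain covers the 2-kb promoter and ≤ 20% of the body
from the 5' end), Edge-End (domain covers 20–40% of the body from the 3'
end), Edge-other (remaining boundary-crossing genes).

## Cell-mixture deconvolution

The estimator treats the swap-calibration curve purely as an empirical
transfer function. For a daughterline pair (A, B) sharing one CpG table:

1. **Swap mixtures.** At each f on the grid (default 1–99%, step 2% at desk
   scale; step 1% gives the full-resolution grid), a uniformly random fraction f
   of CpG sites — exactly round(f·n), selected once per f and shared across
   technical replicates — exchanges uCG identification status between A and
   B. Swapping is an involution and deterministic under its seed.
2. **Statistic.** uCG calls are intersected across technical replicates
   ("identified in all technical replicates"); the statistic is the fraction
   of those calls inside the motherline PMD set that fall within the
   daughterline's unique 2-cell-PMDs. Mean and SD at each f come from
   resampled site subsets (default 200 resamples of 1% of the original uCG
   sites; 1000 at full scale).
3. **Inversion.** The parental sample's statistic, computed with the same
   functional, is inverted through the curve by piecewise-linear
   interpolation; out-of-range observations clamp to the nearest endpoint
   (flagged), non-monotone segments report every crossing (flagged
   ambiguous). The estimated daughterline share is 1 − f̂, with an
   uncertainty propagated from the resampling SD through the local slope.

Two open points were resolved in favour of invertibility and validated by
recovery on true read-level mixtures (Poisson thinning of the two pure read
processes):

* The unique 2-cell-PMDs and the motherline reference are held **fixed** at
  the pure-daughterline regions by default. Re-calling PMDs de novo inside
  every swap mixture (available via `recompute_pmds=True`) makes the
  cell-specific domains vanish near f ≈ 0.5 — their identified-uCG window
  fractions drop below the 30% threshold — leaving the curve undefined
  exactly where it must be inverted.
* The motherline intersection filters uCG **sites** (site-level restriction
  to the motherline PMD set), not whole regions.

Using replicate-intersected calls matters quantitatively: a single-replicate
presence/absence call saturates (P(call) = 1 − e^(−λp) at coverage λ and
mixing p), which biases mid-range estimates upward; the two-replicate
intersection squares the per-replicate probability and keeps the transfer
nearly linear at λ = 3. Recovery across p ∈ {0.1, 0.25, 0.5, 0.75, 0.9}
achieves a mean absolute error of ~0.03 under the default synthetic
conditions (measured by `scripts/acceptance.py`, 5 independent genomes).

## Expression and differential statistics

**Normalization.** Per gene-type stratum, genes with ≥ 5 reads in ≥ 1 sample
are kept; each sample's stratum counts are scaled so its upper quartile of
kept-gene counts matches the geometric mean of the per-sample upper quartiles
(the reference choice is ours; the method name alone does not fix it).
RPKM uses the scaled counts and scaled total library; log2 with a default
pseudocount of 0.25 (0 reproduces the textbook closed form). Strata with
fewer than four expressed genes pass through unscaled with a warning.

**Reliability filter.** Per 1-kb region, one-way ANOVA with biological
sample as the factor and technical replicates as residual; regions with BH
q < 0.05 are "technically reliable". Incomplete regions are excluded and
counted.

**DHR model.** Per region, ordinary least squares of
technical-replicate-averaged h-density on categorical cell type, condition
and CpG identity (per-CpG intercepts as a blocking factor — the alternative
reading of "cytosine ID", a positional covariate, is not provided). Type-II
F tests per non-blocking term, BH across regions per term, Tukey HSD on the
significant regions for the factor's level pairs. Regions with a single CpG
simply lose the blocking factor; rank-deficient designs are skipped and
logged.

**DHG test.** Paired t over a gene's CpG sites, strata analyzed separately,
BH within stratum. Zero-variance conventions: identical vectors give p = 1;
a constant non-zero difference gives p = 0; fewer than two pairs skips the
gene.

**DEG test.** An exact conditional two-group negative-binomial test at
*known* dispersion (default 1e-4). With group sums S_g ~ NB(size n_g/φ),
the conditional law of the split given the total is free of the mean —
P(s) ∝ C(s + r_A − 1, s)·C(t − s + r_B − 1, t − s) — so the two-sided p is
the double-tail sum of outcome probabilities no larger than the observed one.
Fixing the dispersion removes the estimation step entirely and makes the test
fully specifiable; as φ → 0 it converges to the exact binomial split of a
Poisson total, which the tests verify numerically. Library sizes are
equalized by scaling to the geometric-mean library before summing. A gene is
significant with BH q < 0.05 and |log2 FC| > 0.5 (fold changes use a 0.5
pseudocount per group mean).

**Influence model.** Gaussian OLS of log2 expression on binary predictors
{5hmCH status, PMD-inside, PMD-edge, enhancer overlap} plus the 5hmCH ×
PMD-status interaction, with explicit baselines (no 5hmCH; outside PMDs; no
enhancer; 5hmCH-free genes outside PMDs for the interaction). Collinear
columns are dropped with a warning. Coefficients are checked against the
closed-form normal equations and, on synthetic data, against the planted
generative effects (natural-log betas divided by ln 2).

**Enrichment.** All Fisher tests store their 2×2 table; the odds ratio gets
a Haldane–Anscombe 0.5 correction only when a cell is zero (flagged), while
the p-value always comes from the exact uncorrected table and equals
hypergeometric enumeration. Gene-level 5hmCH enrichment gates on the conventional unadjusted
rule (OR > 1, unadjusted p < 0.05) with a BH q reported alongside; non-gene
elements are tested per CH context and the odds ratios averaged.
Replication timing is binned at 1 Mb and split into five rank quantiles
(group 1 = highest signal = earliest; ties break by genomic order).
Permutation overlap p-values use (1 + #{null ≥ obs}) / (n_perm + 1).

## Synthetic data: what it emulates and what it does not

The generator produces, deterministically under its seed: a CpG landscape
(background Poisson process, mean spacing 100 bp, plus 1-kb CGI clusters at
8× density), assembly gaps (optional), non-overlapping gene models with
exon/UTR structure, enhancers of three classes placed uniformly (often
intragenic, as in real genomes), a smooth low-frequency replication-timing
field, per-cell-type methylomes with planted PMDs (uCG probability 0.45
inside / 0.12 outside, matching intermediate-methylation domains), 5hmCG
seeded at enhancers and gene 3' ends (0.35 vs 0.03 background), 5hmCH drawn
from candidate CH sites with intron preference and a 1.2 coding-strand odds,
TOP-seq-style reads (Poisson λ = 3 per tagged site, uniform 0–3 nt read-start
offset, site-level Poisson noise ε = 0.01λ), and negative-binomial expression
whose log-means carry the configured covariate effects with a gene-length
offset.

Planted PMDs keep ≥ 30 kb apart so the merge rule cannot fuse two truths,
and shared-versus-specific assignment is deterministic-proportional with
specific domains rotating over cell types — every cell type owns specific
PMDs whenever enough are planted, which is the premise of the 2-cell-PMD
method (deconvolution scenarios cap domain length at 300 kb so a 4-Mb genome
holds enough domains for both cell types). Biological replicates redraw the
per-site Bernoulli states given the planted domains; technical replicates
redraw only the read sampling.

Not emulated: sequence content (no FASTA; the pipeline's entry point is
post-alignment site counts), mappability and duplicate structure, per-library
depth variation beyond Poisson, chromatin-state correlation between
neighbouring sites, and any coupling between replication timing and the
methylome. Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistics under these idealized
conditions, not performance on real libraries.

## Problem sizes and numerical conventions

The test suite and the acceptance script run on desk-scale genomes chosen as
the package's own defaults: 2–5 Mb chromosomes for module tests, 10 Mb for
planted-PMD recovery, 4 Mb × 5 independent genomes for deconvolution, 50
random ≤ 1-Mb chromosomes for the caller/oracle comparison, 50 replicates ×
200 units for the null calibration of the differential tests and 100
simulations for effect recovery. Ties in read-to-site assignment resolve to
the nearest site; quantile ties in replication grouping break by genomic
order; every stochastic routine takes an explicit seed or Generator.
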