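# Methods

## Model and procedure

`rotspeaks` tests, for each candidate peak, whether read enrichment
differs between two conditions, without distributional assumptions on
the counts. The per-peak statistic family is

    d_α(g) = |x̄_g^i − x̄_g^j| / (α₁ + α₂·s_g),   α₁ ≥ 0, α₂ ∈ {0, 1},

with s_g the pooled two-sample standard error

    s_g = sqrt(s_p² · (1/n_i + 1/n_j)),
    s_p² = ((n_i−1)s_i² + (n_j−1)s_j²) / (n_i+n_j−2).

This definition makes α = (0, 1) reduce exactly to the classical
equal-variance two-sample |t| (verified against an independent
implementation in the test suite), and α = (α₁, 0) a pure
mean-difference ranking. s_i², s_j² are unbiased (ddof = 1) sample
variances, so each condition needs at least two samples.

The free parameters (α, k) are chosen to maximize

    Z_k(d_α) = (R_k(d_α) − R_k⁰(d_α)) / s_k(d_α)

over a grid. For each of B bootstrap pairs, both members resample
samples with replacement *within* each condition (group sizes
preserved); R_k is the mean fraction of the k top-ranked peaks shared
by the two members of a pair. Null pairs first permute the condition
labels across all samples (independently per member), then bootstrap
within the permuted groups, destroying any real group signal while
preserving the resampling noise; R_k⁰ is their mean overlap. s_k is the
sample (ddof = 1) standard deviation of the B bootstrap overlaps. The
same B resampled index sets are shared by every grid cell, so cells
differ only through the statistic, not through resampling luck.

Degenerate grid cells (s_k = 0 with unequal means) are excluded from
the arg-max; s_k = 0 with equal means gives Z = 0. Ties in d are broken
by ascending feature index, and grid ties resolve in grid order, so the
whole procedure is deterministic given the seed. Inside the resampling
machinery a vanishing denominator is tolerated (0/0 → 0, x/0 → ranked
first); on the observed data it raises an error naming the feature,
since it means α₁ = 0 with a peak constant in both groups.

### Significance

With α fixed at the optimum, n_perm label permutations yield null
statistic vectors. Per-feature p-values pool all null values:

    p(g) = (1 + #{null ≥ d_g}) / (1 + n_perm·n).

The FDR of feature g averages, over permutations, the count of null
statistics ≥ d_g divided by the count of observed statistics ≥ d_g,
capped at 1. Monotonicity along the ranking is enforced with a running
maximum from the most significant feature downward — the conservative
direction (a feature's FDR can only be raised, never lowered, by a
noisier feature above it). Note the permutation floor: with r replicates
per group only C(2r, r)/2 distinct label splits exist, so with 3 + 3
samples no FDR below ~0.1 is achievable; ≥4 replicates per condition
are needed for FDR < 0.05 calls.

### Defaults

| parameter | default | rationale |
|---|---|---|
| α grid | α₂=1 with α₁ ∈ {0, 0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 1, 1.5, 2, 3, 5}; plus (1, 0) | spans the t-to-fold-change family |
| k grid | {25, 50, …, 5000} truncated at n/2 | log-ish ladder; overlap beyond n/2 is uninformative |
| B | 1000 | stable Z at desk scale; configurable |
| n_perm | 1000 (min 10) | stable FDR; configurable |
| FDR threshold | 0.05 | conventional |
| MAPQ threshold | 15 | standard low-quality cutoff for chromatin data |

## Peak workflow

Coordinates are 0-based half-open (BED convention); narrowPeak is
BED6+4. The candidate list is the union of all input peak sets with
overlapping *or book-ended* intervals merged (bedtools default;
implemented via pyranges `merge(slack=0)`). Counting uses pysam: in
fragment mode (paired-end ATAC) each properly paired template — leftmost
mate start to leftmost start + TLEN — is counted once per peak it
overlaps by ≥ 1 bp; in read mode each passing alignment counts.
Duplicates, secondary/supplementary alignments and reads below the MAPQ
threshold are excluded (configurable). The BAM is streamed once in full
and fragments are assigned to peaks through an interval tree, so a
fragment whose mates both lie outside a peak but whose insert spans it
is still counted. Strand is ignored — accessibility and occupancy are
strandless. The ≥ 1 bp overlap rule is a convention; no minimum-overlap
fraction is imposed.

Normalization is median-of-ratios: per sample, the median over
all-positive features of count / geometric-mean-across-samples.
Features containing any zero are excluded from the median (their
geometric mean is 0). The median of the linear ratios is taken; for an
even feature count this interpolates arithmetically where DESeq2
interpolates in log space — a difference far below counting noise.
log2 fold-changes add a pseudocount of 0.5 to each group mean to keep
zero-count groups finite; the statistic itself uses the unlogged mean
difference.

## Synthetic benchmark

The generator emulates a downsampling benchmark for histone-mark
ChIP-seq. Defaults: 20 000 non-overlapping peaks (log-normal widths,
median 1 kb, log-SD 0.5, minimum 150 bp; exponential gaps, mean 5 kb)
on a synthetic chromosome; per-peak base counts negative binomial with
mean 500 and dispersion 0.3 (var = μ + 0.3μ²), chosen as typical of
strong ChIP enrichment at desk scale. Half the peaks are uniformly
assigned "true differential" labels, split evenly over 10 intensity
categories (10%, 20%, …, 100% *difference* in signal): a category-c
peak's treatment count is Binomial(ref, 1 − c/100) — category 100 means
complete signal loss in the treatment. Five replicates per condition
each thin all counts by an independent Uniform(10%, 30%) fraction
(binomial thinning, the count-level equivalent of subsampling reads),
and every count is finally multiplied by an independent log-normal
factor with log-SD 0.25 — the biological-noise layer.

Where the original benchmark design downsampled real aligned reads,
this generator is parametric: downstream analysis consumes only counts
per fixed peak regions, so the statistical structure (signal mean and
dispersion, binomial thinning, multiplicative noise) is preserved while
the read-level detail (fragment positions, peak shape, mappability) is
not. Consequently passing tests demonstrate correct recovery of
count-level differential signal under replicate and biological noise;
they say nothing about read-level artifacts (duplicates, GC bias,
blacklist regions), which are upstream concerns.

All randomness in the generator and in the test flows from a single
seed through spawned child streams; rerunning reproduces output files
byte for byte.

## Evaluation

Against synthetic truth: significant peaks (FDR < threshold) are
intersected with true peaks under two criteria — any ≥ 1 bp overlap, or
≥ 25% of the true peak's length. Each true peak counts at most once;
significant peaks overlapping no true differential peak are false
positives. ROC curves sweep the score (statistic d, or 1 − FDR when raw
statistics are absent; both give the same curve up to monotone
transformation) over the differential/non-differential labels, with
trapezoidal AUC; the implementation is checked against the
Mann–Whitney U-statistic identity in the tests.

Against expression: peaks are annotated to the gene whose TSS is
nearest the peak midpoint (distance 0 if the TSS lies inside the peak;
ties go to the lexicographically smallest gene id — TSS distance is the
conventional choice for promoter-proximal marks). For each top-N cutoff
(N = 100, 200, …, 2000 by default) the Pearson correlation between peak
log10 fold-change and expression log10 fold-change is computed over
contributing genes; several peaks mapping to one gene contribute the
mean of their log10 fold-changes (averaging on the log scale keeps the
quantity symmetric in direction). Cutoffs with fewer than three genes
report a missing value rather than an unstable correlation. The
expression fold-change table is an input, already computed by whatever
differential-expression route fits the data; it is log10-transformed on
read if given as plain ratios.

## Problem sizes used by the shipped suites

The test and acceptance runs use desk-scale configurations chosen to
exercise every code path with stable statistics: the pure-null
error-rate check uses 2000 features, 5 + 5 samples, B = 100, n_perm =
100, averaged over 10 seeds; the power check uses the scaled benchmark
(2000 peaks, 100 differential per category) with B = 200, n_perm = 200.
The benchmark-design checks run the full default 20 000-peak generator,
which is cheap. B = 1000 remains the analysis default.

## Known limitations

- Exactly two conditions; no paired designs or covariates.
- The permutation FDR floor at small replicate numbers (above).
- The null convention (labels permuted, then bootstrap within permuted
  groups) is one of several defensible randomization schemes; it keeps
  null and bootstrap overlaps on the same resampling footing.
- The benchmark's parametric counts do not model inter-peak correlation
  or copy-number structure.
- Fragment counting requires proper pairs with TLEN set; single-end
  data should use read mode.
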