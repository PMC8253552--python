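# rotspeaks

Reproducibility-optimized differential peak calling for ATAC-seq and
ChIP-seq data with replicates.

Given per-sample peak calls (BED/narrowPeak) and per-sample read counts
(from coordinate-sorted BAMs or a ready count matrix), `rotspeaks` finds
peaks whose read enrichment differs between two biological conditions.
It is a *two-step* caller: region discovery is left to an external peak
caller (e.g. MACS2); this package builds the merged candidate peak list,
counts reads, normalizes, tests, and ranks.

## The statistic

Features (peaks) are ranked by a family of t-type statistics

```
d_α(g) = |x̄_g^i − x̄_g^j| / (α₁ + α₂·s_g)
```

where `x̄_g^i`, `x̄_g^j` are the mean normalized counts of peak *g* in
conditions *i* and *j*, and `s_g` is the pooled two-sample standard
error. The family interpolates between a fold-change-like ranking
(α₂ = 0) and the ordinary t statistic (α = (0, 1)).

Rather than fixing α, the method selects the (α, k) that maximizes the
reproducibility z-score

```
Z_k(d_α) = (R_k(d_α) − R_k⁰(d_α)) / s_k(d_α)
```

where `R_k` is the average overlap of the *k* top-ranked peaks across B
pairs of within-group bootstrap datasets,

```
R_k^(b)(d_α) = #{g : r_g(α, D₁^(b)) ≤ k and r_g(α, D₂^(b)) ≤ k} / k ,
```

`R_k⁰` is the same quantity on label-permuted (null) pairs, and `s_k` is
the bootstrap standard deviation of the overlap. The statistic that
ranks peaks most consistently under resampling — relative to what chance
alone achieves — wins. Significance of the optimized ranking is assessed
by a label-permutation FDR. Counts are normalized with DESeq2-style
median-of-ratios size factors (optional; skip it when all samples share
one read pool, as in the synthetic benchmark).

The package also ships the synthetic benchmark generator used to
validate the method (binomial downsampling of "true differential" peaks
across 10 intensity categories, 5 thinned replicates per condition, a
log-normal noise layer) and the two evaluation procedures: detection
counts/ROC against synthetic truth, and Pearson correlation of peak
fold-changes with expression fold-changes of nearest genes.

## Worked example

`examples/benchmark_roundtrip.py` simulates a scaled benchmark
(2000 peaks, 100 true differential peaks per intensity category), runs
the full pipeline and scores it against the truth:

```
optimized alpha=(5, 1), k=500, Z=12.3

overlap criterion 1bp: 570 significant, 12 false positives
category :   10   20   30   40   50   60   70   80   90  100
detected :    0    5    9   22   49   82   93   98  100  100
```

Each intensity category holds 100 true differential peaks whose
treatment signal was thinned by the category percentage. Detection
rises with the imposed difference and saturates from ~60% upward, while
only 12 of 1000 non-differential peaks are called — the expected
behaviour for a well-calibrated caller: strong differences are found
almost completely, marginal (10–20%) differences are indistinguishable
from replicate noise.

Other examples: `statistic_optimization.py` (grid optimization on a
spike-in matrix), `merge_count_workflow.py` (peak merging and fragment
counting from BAMs), `expression_correlation.py` (nearest-gene
fold-change correlation).

## Command line

```sh
rotspeaks merge s1.narrowPeak s2.narrowPeak -o candidates.bed
rotspeaks count --peaks candidates.bed s1=s1.bam s2=s2.bam ... -o counts.tsv
rotspeaks test --counts counts.tsv --design design.tsv -o diff.tsv \
    --bed significant.bed --fdr 0.05 --seed 1
rotspeaks simulate --seed 1 --outdir bench/
rotspeaks evaluate --table diff.tsv --truth bench/truth.tsv -o report.tsv
rotspeaks correlate --table diff.tsv --genes genes.tsv \
    --expression expr.tsv -o curve.tsv
```

`design.tsv` maps `sample_id<TAB>condition` (exactly two conditions,
≥2 samples each). Every stochastic subcommand takes `--seed` and is
bit-reproducible under it; each run writes a provenance JSON.

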