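"""Synthetic differential-peak benchmark with known truth labels.

The benchmark emulates a downsampling design for histone-mark ChIP-seq:
a reference condition of candidate peaks with read counts, and a
treatment condition created by thinning the reads of "true differential"
peaks across 10 intensity categories (10%, 20%, ..., 100% difference in
signal). Replicates per condition are produced by randomly thinning
10-30% of each sample's reads, and a multiplicative log-normal noise
layer emulates biological variability.

Where the original design downsampled real reads, this generator draws
per-peak base counts from a negative binomial — the downstream analysis
consumes only counts per peak, so the statistical structure (mean/
dispersion of peak signal, binomial thinning) is what matters.

All randomness flows from a single seed; re-running reproduces the
output files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import CountMatrix
from .matrix import GroupDesign
from .peaks import PeakSet

__all__ = [
    "BenchConfig",
    "simulate_reference",
    "assign_truth",
    "downsample_treatment",
    "make_replicates",
    "add_noise",
    "emit_benchmark",
]

REFERENCE = "reference"
TREATMENT = "treatment"


@dataclass
class BenchConfig:
    """Benchmark design parameters.

    Defaults reproduce the standard design: 20 000 candidate peaks, half
    of them truly differential, split evenly over 10 intensity
    categories, with 5 replicates per condition thinned by a random
    10-30%.
    """

    n_peaks: int = 20000
    n_differential: int = 10000
    n_categories: int = 10
    n_per_category: int = 1000
    n_replicates: int = 5
    replicate_thinning: tuple[float, float] = (0.10, 0.30)
    noise_sigma: float = 0.25
    # negative binomial base counts: var = mean + dispersion * mean^2
    count_mean: float = 500.0
    count_dispersion: float = 0.3
    # log-normal peak widths (bp)
    width_median: float = 1000.0
    width_log_sd: float = 0.5
    min_width: int = 150
    gap_mean: float = 5000.0
    chrom_name: str = "chrS"
    genome_length: int | None = None  # None: genome sized to fit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential != self.n_categories * self.n_per_category:
            raise ValueError(
                "n_differential must equal n_categories * n_per_category"
            )
        if self.n_differential > self.n_peaks:
            raise ValueError("n_differential exceeds n_peaks")
        lo, hi = self.replicate_thinning
        if not 0 <= lo <= hi < 1:
            raise ValueError("replicate_thinning must satisfy 0 <= lo <= hi < 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def categories(self) -> np.ndarray:
        """Percent signal difference per category: 10, 20, ..., 100."""
        step = 100 // self.n_categories
        return np.arange(1, self.n_categories + 1) * step


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_reference(cfg: BenchConfig) -> tuple[PeakSet, np.ndarray]:
    """Lay out non-overlapping peaks on a synthetic chromosome and draw
    per-peak base counts from the configured negative binomial."""
    rng = _rng(np.random.SeedSequence(cfg.seed).spawn(5)[0])
    widths = np.maximum(
        np.round(
            rng.lognormal(np.log(cfg.width_median), cfg.width_log_sd,
                          cfg.n_peaks)
        ).astype(np.int64),
        cfg.min_width,
    )
    gaps = np.maximum(
        np.round(rng.exponential(cfg.gap_mean, cfg.n_peaks)).astype(np.int64),
        1,
    )
    starts = np.cumsum(gaps + np.concatenate([[0], widths[:-1]]))
    ends = starts + widths
    if cfg.genome_length is not None and ends[-1] > cfg.genome_length:
        raise ValueError(
            f"{cfg.n_peaks} peaks need {ends[-1]} bp but genome_length is "
            f"{cfg.genome_length}"
        )
    peaks = PeakSet(
        pd.DataFrame(
            {"chrom": cfg.chrom_name, "start": starts, "end": ends}
        )
    )
    # NB(mean m, dispersion a): var = m + a m^2; shape n = 1/a, p = n/(n+m)
    n_shape = 1.0 / cfg.count_dispersion
    p = n_shape / (n_shape + cfg.count_mean)
    base_counts = rng.negative_binomial(n_shape, p, cfg.n_peaks)
    return peaks, base_counts.astype(np.int64)


def assign_truth(peaks: PeakSet, cfg: BenchConfig, seed) -> pd.DataFrame:
    """Randomly label peaks differential/non-differential and assign
    intensity categories.

    Returns a frame with columns peak_id, label, category, direction;
    exactly ``n_per_category`` differential peaks per category, category
    blank (pandas NA) for non-differential peaks. ``direction`` names the
    condition that loses signal (always the treatment here).
    """
    if len(peaks) != cfg.n_peaks:
        raise ValueError(
            f"peak set has {len(peaks)} peaks, config says {cfg.n_peaks}"
        )
    rng = _rng(seed)
    perm = rng.permutation(cfg.n_peaks)
    category = np.zeros(cfg.n_peaks, dtype=np.int64)
    cats = cfg.categories
    for ci, cat in enumerate(cats):
        sel = perm[ci * cfg.n_per_category:(ci + 1) * cfg.n_per_category]
        category[sel] = cat
    label = np.where(category > 0, "differential", "non_differential")
    truth = pd.DataFrame(
        {
            "peak_id": peaks.peak_ids,
            "label": label,
            "category": pd.array(
                np.where(category > 0, category, 0), dtype="Int64"
            ),
            "direction": np.where(category > 0, TREATMENT, ""),
        }
    )
    truth.loc[truth["label"] == "non_differential", "category"] = pd.NA
    return truth


def downsample_treatment(
    reference_counts: np.ndarray, truth: pd.DataFrame, seed
) -> np.ndarray:
    """Build the treatment condition: binomially thin each differential
    peak's count with retention 1 - category/100; copy the rest.

    Category 100 (complete loss) yields zero counts; category 10 retains
    90% of the signal on average.
    """
    reference_counts = np.asarray(reference_counts)
    if len(reference_counts) != len(truth):
        raise ValueError("counts and truth table differ in length")
    rng = _rng(seed)
    category = truth["category"].to_numpy(dtype=float, na_value=0.0)
    retention = 1.0 - category / 100.0
    return rng.binomial(reference_counts, retention).astype(np.int64)


def make_replicates(
    sample_counts: np.ndarray, cfg: BenchConfig, seed
) -> np.ndarray:
    """Thin a condition's counts into ``n_replicates`` simulated
    biological replicates.

    Each replicate removes a random fraction f ~ Uniform(lo, hi) of the
    reads (binomial thinning with retention 1 - f), emulating independent
    library downsampling.
    """
    sample_counts = np.asarray(sample_counts)
    rng = _rng(seed)
    lo, hi = cfg.replicate_thinning
    reps = np.empty((len(sample_counts), cfg.n_replicates), dtype=np.int64)
    for r in range(cfg.n_replicates):
        f = rng.uniform(lo, hi)
        reps[:, r] = rng.binomial(sample_counts, 1.0 - f)
    return reps


def add_noise(counts: np.ndarray, cfg: BenchConfig, seed) -> np.ndarray:
    """Multiply each count by an independent log-normal factor
    (log-SD = ``noise_sigma``) and round — the biological-noise layer."""
    counts = np.asarray(counts)
    if cfg.noise_sigma == 0:
        return counts.copy()
    rng = _rng(seed)
    factors = rng.lognormal(0.0, cfg.noise_sigma, counts.shape)
    return np.round(counts * factors).astype(np.int64)


def benchmark_design(cfg: BenchConfig) -> GroupDesign:
    """The 2 x n_replicates sample-to-condition design of the benchmark."""
    assignment = {
        f"{REFERENCE}_{r + 1}": REFERENCE for r in range(cfg.n_replicates)
    }
    assignment.update(
        {f"{TREATMENT}_{r + 1}": TREATMENT for r in range(cfg.n_replicates)}
    )
    return GroupDesign(assignment)


def emit_benchmark(
    cfg: BenchConfig, outdir: str | Path | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate the full benchmark; optionally write its files.

    Pipeline: reference layout and counts -> truth labels -> treatment
    downsampling -> replicate thinning (both conditions) -> noise layer.
    Returns the count matrix (reference replicates first, then treatment)
    and the truth table. With ``outdir``, writes counts.tsv, truth.tsv,
    truth.bed and design.tsv.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(5)
    peaks, ref_counts = simulate_reference(cfg)
    truth = assign_truth(peaks, cfg, ss[1])
    trt_counts = downsample_treatment(ref_counts, truth, ss[2])
    ss_rep = ss[3].spawn(2)
    ref_reps = make_replicates(ref_counts, cfg, ss_rep[0])
    trt_reps = make_replicates(trt_counts, cfg, ss_rep[1])
    raw = np.column_stack([ref_reps, trt_reps])
    noisy = add_noise(raw, cfg, ss[4])
    sample_ids = [f"{REFERENCE}_{r + 1}" for r in range(cfg.n_replicates)]
    sample_ids += [f"{TREATMENT}_{r + 1}" for r in range(cfg.n_replicates)]
    counts = CountMatrix(
        peaks=peaks,
        counts=noisy,
        sample_ids=np.array(sample_ids, dtype=object),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts.to_tsv(outdir / "counts.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        write_truth_bed(peaks, truth, outdir / "truth.bed")
        benchmark_design(cfg).to_tsv(outdir / "design.tsv")
    return counts, truth


def write_truth_bed(peaks: PeakSet, truth: pd.DataFrame, path) -> None:
    """BED of the peaks with name = label[:category]."""
    names = np.where(
        truth["label"] == "differential",
        truth["label"].astype(str) + ":"
        + truth["category"].astype(str),
        truth["label"].astype(str),
    )
    out = peaks.frame[["chrom", "start", "end"]].copy()
    out["name"] = names
    out.to_csv(path, sep="\t", header=False, index=False)
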