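"""Reproducibility-optimized test statistic (ROTS) for two-group designs.

The method ranks genomic features with a family of t-type statistics

    d_alpha(g) = |xbar_i(g) - xbar_j(g)| / (alpha1 + alpha2 * s(g)),

where s(g) is the pooled two-sample standard error, and selects the
(alpha, k) pair that maximizes the reproducibility z-score

    Z_k(d_alpha) = (R_k(d_alpha) - R0_k(d_alpha)) / s_k(d_alpha).

R_k is the average overlap of the k top-ranked features across B pairs of
within-group bootstrap datasets; R0_k is the same quantity on
label-permuted (null) pairs; s_k is the bootstrap standard deviation of
the overlap. alpha2 = 0 gives a pure mean-difference (fold-change-like)
ranking; alpha1 = 0, alpha2 = 1 gives the ordinary equal-variance t
ranking. Significance is assessed by a label-permutation FDR at the
optimized alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import DataMatrix, GroupDesign

__all__ = [
    "AlphaParams",
    "RotsConfig",
    "FeatureStat",
    "RotsResult",
    "default_alpha_grid",
    "default_k_grid",
    "t_type_statistic",
    "bootstrap_pair",
    "null_pair",
    "reproducibility",
    "z_score",
    "optimize",
    "permutation_fdr",
    "fdr_from_null",
]


@dataclass(frozen=True)
class AlphaParams:
    """Parameters (alpha1, alpha2) of the t-type statistic family.

    alpha2 is restricted to {0, 1}: 0 ranks by absolute mean difference
    scaled by 1/alpha1, 1 gives a regularized t statistic.
    """

    alpha1: float
    alpha2: int

    def __post_init__(self) -> None:
        if self.alpha1 < 0:
            raise ValueError("alpha1 must be non-negative")
        if self.alpha2 not in (0, 1):
            raise ValueError("alpha2 must be 0 or 1")
        if self.alpha1 == 0 and self.alpha2 == 0:
            raise ValueError("(alpha1, alpha2) = (0, 0) is degenerate")


def default_alpha_grid() -> list[AlphaParams]:
    """Regularized-t ladder plus the pure mean-difference statistic."""
    grid = [
        AlphaParams(a1, 1)
        for a1 in (0, 0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 1, 1.5, 2, 3, 5)
    ]
    grid.append(AlphaParams(1, 0))
    return grid


_K_LADDER = (25, 50, 100, 200, 300, 500, 750, 1000, 1500, 2000, 2500, 5000)


def default_k_grid(n_features: int) -> list[int]:
    """Top-list sizes: a geometric-ish ladder truncated at n_features / 2."""
    cap = max(1, n_features // 2)
    grid = [k for k in _K_LADDER if k <= cap]
    return grid or [cap]


@dataclass
class RotsConfig:
    """Resampling and optimization settings; ``seed`` fixes every random
    draw so results are bit-reproducible."""

    b: int = 1000
    k_grid: list[int] | None = None
    alpha_grid: list[AlphaParams] | None = None
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b < 2:
            raise ValueError("b (number of bootstrap pairs) must be >= 2")

    def resolved_k_grid(self, n_features: int) -> list[int]:
        if self.k_grid is None:
            return default_k_grid(n_features)
        bad = [k for k in self.k_grid if not 1 <= k <= n_features]
        if bad:
            raise ValueError(
                f"k values {bad} outside [1, {n_features}]"
            )
        return list(self.k_grid)

    def resolved_alpha_grid(self) -> list[AlphaParams]:
        if self.alpha_grid is None:
            return default_alpha_grid()
        if not self.alpha_grid:
            raise ValueError("alpha_grid must be non-empty")
        return list(self.alpha_grid)


@dataclass
class FeatureStat:
    """Per-feature statistic values with their ranking.

    ``ranks`` is a permutation of 1..n (1 = largest d); ties in d are
    broken by ascending feature index so ranking is deterministic.
    """

    feature_ids: np.ndarray
    d: np.ndarray
    ranks: np.ndarray
    mean_diff: np.ndarray  # signed xbar_i - xbar_j
    se: np.ndarray

    def top(self, k: int) -> np.ndarray:
        return self.feature_ids[self.ranks <= k]


@dataclass
class RotsResult:
    """Optimized statistic on the observed data plus significance estimates."""

    stat: FeatureStat
    alpha: AlphaParams
    k: int
    z: float
    reproducibility: float
    pvalue: np.ndarray
    fdr: np.ndarray
    z_grid: np.ndarray = field(repr=False, default=None)  # (alpha, k) grid of Z


# ---------------------------------------------------------------------------
# statistic


def _group_moments(x: np.ndarray, idx: np.ndarray):
    sub = x[:, idx]
    return sub.mean(axis=1), sub.var(axis=1, ddof=1)


def _pooled_se(vi, vj, ni: int, nj: int) -> np.ndarray:
    pooled = ((ni - 1) * vi + (nj - 1) * vj) / (ni + nj - 2)
    return np.sqrt(pooled * (1.0 / ni + 1.0 / nj))


def _d_values(
    mean_diff: np.ndarray, se: np.ndarray, alpha: AlphaParams
) -> np.ndarray:
    """Lenient d: 0/0 -> 0, x/0 -> +inf (ranked on top).

    Resampled datasets can produce zero standard errors; inside the
    resampling machinery those features are ranked first rather than
    aborting the run.
    """
    denom = alpha.alpha1 + alpha.alpha2 * se
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(mean_diff) / denom
    return np.nan_to_num(d, nan=0.0, posinf=np.inf)


def _ranks(d: np.ndarray) -> np.ndarray:
    order = np.lexsort((np.arange(d.size), -d))
    ranks = np.empty(d.size, dtype=np.int64)
    ranks[order] = np.arange(1, d.size + 1)
    return ranks


def t_type_statistic(
    data: DataMatrix, design: GroupDesign, alpha: AlphaParams
) -> FeatureStat:
    """Compute d_alpha for every feature of the observed data.

    Raises if any feature has a zero denominator (possible only when
    alpha1 = 0 and the pooled standard error vanishes).
    """
    idx_i, idx_j = design.group_indices(data.sample_ids)
    mi, vi = _group_moments(data.values, idx_i)
    mj, vj = _group_moments(data.values, idx_j)
    se = _pooled_se(vi, vj, len(idx_i), len(idx_j))
    denom = alpha.alpha1 + alpha.alpha2 * se
    if (denom <= 0).any():
        bad = data.feature_ids[denom <= 0][0]
        raise ValueError(
            f"zero denominator for feature {bad!r}: alpha1 = 0 and the "
            "pooled standard error is 0 (constant values in both groups)"
        )
    mean_diff = mi - mj
    d = np.abs(mean_diff) / denom
    return FeatureStat(
        feature_ids=data.feature_ids,
        d=d,
        ranks=_ranks(d),
        mean_diff=mean_diff,
        se=se,
    )


# ---------------------------------------------------------------------------
# resampling


def _resample_columns(rng, idx_i, idx_j):
    """Within-group bootstrap: sample columns with replacement inside each
    condition, preserving per-condition sizes."""
    bi = rng.choice(idx_i, size=len(idx_i), replace=True)
    bj = rng.choice(idx_j, size=len(idx_j), replace=True)
    return bi, bj


def _permuted_groups(rng, idx_i, idx_j):
    """Destroy group structure: permute condition labels across all samples."""
    pool = np.concatenate([idx_i, idx_j])
    perm = rng.permutation(pool)
    return perm[: len(idx_i)], perm[len(idx_i):]


def _submatrix(data: DataMatrix, cols: np.ndarray) -> DataMatrix:
    # Resampled columns repeat sample ids; disambiguate for the invariant.
    ids = [f"{data.sample_ids[c]}#{p}" for p, c in enumerate(cols)]
    return DataMatrix(
        values=data.values[:, cols],
        feature_ids=data.feature_ids,
        sample_ids=np.array(ids, dtype=object),
    )


def bootstrap_pair(
    data: DataMatrix, design: GroupDesign, seed
) -> tuple[DataMatrix, DataMatrix]:
    """Two independent within-group bootstrap resamples of ``data``.

    Columns of each member are ordered group-i samples then group-j
    samples; pair with a design mapping the first n_i columns to
    condition i when re-testing.
    """
    rng = np.random.default_rng(seed)
    idx_i, idx_j = design.group_indices(data.sample_ids)
    members = []
    for _ in range(2):
        bi, bj = _resample_columns(rng, idx_i, idx_j)
        members.append(_submatrix(data, np.concatenate([bi, bj])))
    return members[0], members[1]


def null_pair(
    data: DataMatrix, design: GroupDesign, seed
) -> tuple[DataMatrix, DataMatrix]:
    """Like :func:`bootstrap_pair` but condition labels are permuted across
    samples, independently in each member, before the within-group
    bootstrap — the pair carries no real group signal."""
    rng = np.random.default_rng(seed)
    idx_i, idx_j = design.group_indices(data.sample_ids)
    members = []
    for _ in range(2):
        pi, pj = _permuted_groups(rng, idx_i, idx_j)
        bi, bj = _resample_columns(rng, pi, pj)
        members.append(_submatrix(data, np.concatenate([bi, bj])))
    return members[0], members[1]


def reproducibility(stat_a: FeatureStat, stat_b: FeatureStat, k: int) -> float:
    """Fraction of the k top-ranked features shared by two rankings."""
    if not np.array_equal(stat_a.feature_ids, stat_b.feature_ids):
        raise ValueError("rankings are over different feature sets")
    n = len(stat_a.feature_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} outside [1, {n}]")
    return np.count_nonzero((stat_a.ranks <= k) & (stat_b.ranks <= k)) / k


def z_score(r_boot: np.ndarray, r_null: np.ndarray) -> float:
    """Reproducibility z-score: (mean(R) - mean(R0)) / sd(R).

    sd is the sample (ddof=1) standard deviation of the bootstrap
    overlaps. A zero sd yields 0 when the means agree, otherwise a signed
    infinity that optimization excludes.
    """
    r_boot = np.asarray(r_boot, dtype=float)
    r_null = np.asarray(r_null, dtype=float)
    if r_boot.size < 2 or r_boot.size != r_null.size:
        raise ValueError("need two equal-length vectors of length >= 2")
    num = r_boot.mean() - r_null.mean()
    sd = r_boot.std(ddof=1)
    if sd == 0:
        return 0.0 if num == 0 else float(np.sign(num) * np.inf)
    return float(num / sd)


# ---------------------------------------------------------------------------
# optimization


def _member_moments(x, cols_i, cols_j):
    mi, vi = _group_moments(x, cols_i)
    mj, vj = _group_moments(x, cols_j)
    return mi - mj, _pooled_se(vi, vj, len(cols_i), len(cols_j))


def optimize(
    data: DataMatrix, design: GroupDesign, cfg: RotsConfig
) -> RotsResult:
    """Grid-search (alpha, k) for maximal reproducibility z-score, then
    score the observed data at the winner and attach permutation FDR.

    The same B bootstrap (and B null) column index sets are reused for
    every grid cell, so cells differ only through the statistic. Grid
    ties and the arg-max are resolved in (alpha_grid, k_grid) order.
    """
    x = data.values
    idx_i, idx_j = design.group_indices(data.sample_ids)
    alpha_grid = cfg.resolved_alpha_grid()
    k_grid = cfg.resolved_k_grid(data.n_features)

    ss = np.random.SeedSequence(cfg.seed)
    rng_boot, rng_null, ss_fdr = ss.spawn(3)
    rng_boot = np.random.default_rng(rng_boot)
    rng_null = np.random.default_rng(rng_null)

    n_a, n_k, b_total = len(alpha_grid), len(k_grid), cfg.b
    r_boot = np.empty((n_a, n_k, b_total))
    r_null = np.empty((n_a, n_k, b_total))
    k_arr = np.asarray(k_grid)

    for b in range(b_total):
        for target, rng, permute in (
            (r_boot, rng_boot, False),
            (r_null, rng_null, True),
        ):
            pair_ranks = []
            for _member in range(2):
                gi, gj = (idx_i, idx_j)
                if permute:
                    gi, gj = _permuted_groups(rng, idx_i, idx_j)
                ci, cj = _resample_columns(rng, gi, gj)
                md, se = _member_moments(x, ci, cj)
                pair_ranks.append(
                    [_ranks(_d_values(md, se, a)) for a in alpha_grid]
                )
            for ai in range(n_a):
                r1, r2 = pair_ranks[0][ai], pair_ranks[1][ai]
                both = np.maximum(r1, r2)  # in both top-k iff max rank <= k
                both.sort()
                target[ai, :, b] = np.searchsorted(both, k_arr, side="right") / k_arr

    mean_boot = r_boot.mean(axis=2)
    mean_null = r_null.mean(axis=2)
    sd_boot = r_boot.std(axis=2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mean_boot - mean_null) / sd_boot
    degenerate = sd_boot == 0
    z[degenerate & (mean_boot == mean_null)] = 0.0
    z[degenerate & (mean_boot != mean_null)] = -np.inf  # excluded
    if not np.isfinite(z).any():
        raise ValueError("all (alpha, k) grid cells are degenerate")

    flat = int(np.argmax(z))
    ai, ki = divmod(flat, n_k)
    alpha_opt, k_opt = alpha_grid[ai], k_grid[ki]

    stat = t_type_statistic(data, design, alpha_opt)
    pvalue, fdr = _permutation_fdr_values(
        x, idx_i, idx_j, alpha_opt, stat.d, cfg.n_perm,
        np.random.default_rng(ss_fdr),
    )
    return RotsResult(
        stat=stat,
        alpha=alpha_opt,
        k=k_opt,
        z=float(z[ai, ki]),
        reproducibility=float(mean_boot[ai, ki]),
        pvalue=pvalue,
        fdr=fdr,
        z_grid=z,
    )


# ---------------------------------------------------------------------------
# permutation FDR


def fdr_from_null(
    d_obs: np.ndarray, null_stats: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """(p-value, FDR) from observed statistics and per-permutation nulls.

    p-values pool every null statistic: p(g) = (1 + #{null >= d_g}) /
    (1 + n_perm * n). FDR(g) averages #{null_p >= d_g} / #{obs >= d_g}
    over permutations p, capped at 1, then made monotone non-decreasing
    along decreasing d by a conservative running maximum from the most
    significant feature down.
    """
    d_obs = np.asarray(d_obs, dtype=float)
    n = d_obs.size
    n_perm = len(null_stats)
    obs_sorted = np.sort(d_obs)
    n_ge_obs = n - np.searchsorted(obs_sorted, d_obs, side="left")

    total_null_ge = np.zeros(n)
    for null in null_stats:
        null_sorted = np.sort(np.asarray(null, dtype=float))
        total_null_ge += null_sorted.size - np.searchsorted(
            null_sorted, d_obs, side="left"
        )

    pvalue = (1.0 + total_null_ge) / (1.0 + n_perm * n)
    fdr = np.minimum(total_null_ge / n_perm / n_ge_obs, 1.0)
    order = np.lexsort((np.arange(n), -d_obs))
    fdr[order] = np.maximum.accumulate(fdr[order])
    return pvalue, fdr


def _permutation_fdr_values(x, idx_i, idx_j, alpha, d_obs, n_perm, rng):
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10 for a stable FDR estimate")
    null_stats = []
    for _p in range(n_perm):
        pi, pj = _permuted_groups(rng, idx_i, idx_j)
        md, se = _member_moments(x, pi, pj)
        null_stats.append(_d_values(md, se, alpha))
    return fdr_from_null(d_obs, null_stats)


def permutation_fdr(
    data: DataMatrix,
    design: GroupDesign,
    alpha_opt: AlphaParams,
    cfg: RotsConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (FDR, p-value) by permuting condition labels.

    p-values pool all n_perm x n_features null statistics; the FDR of
    feature g averages, over permutations, the count of null statistics
    >= d_g divided by the count of observed statistics >= d_g, capped at
    1 and monotonized along the observed ranking.
    """
    x = data.values
    idx_i, idx_j = design.group_indices(data.sample_ids)
    stat = t_type_statistic(data, design, alpha_opt)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    pvalue, fdr = _permutation_fdr_values(
        x, idx_i, idx_j, alpha_opt, stat.d, cfg.n_perm, rng
    )
    return fdr, pvalue
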