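"""Scoring differential peak calls.

Two evaluation routes:

* against synthetic truth — per-intensity-category detection counts,
  false positives, and ROC curves over the differential / non-differential
  labels;
* against matched expression data — nearest-gene annotation of peaks and
  the Pearson correlation between peak and gene log10 fold-changes over an
  increasing number of top-ranked peaks.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .peaks import PeakSet

__all__ = [
    "DetectionReport",
    "RocCurve",
    "CorrelationCurve",
    "overlap_truth",
    "roc_curve",
    "annotate_nearest_gene",
    "fc_correlation",
    "read_gene_table",
    "read_expression_table",
]


@dataclass
class DetectionReport:
    """Detection counts of significant peaks against synthetic truth."""

    tp_per_category: dict[int, int]
    false_positives: int
    n_significant: int
    criterion: str
    fdr_threshold: float

    @property
    def true_positives(self) -> int:
        return sum(self.tp_per_category.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": c, "true_positives": n}
            for c, n in sorted(self.tp_per_category.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


@dataclass
class CorrelationCurve:
    """Pearson r between peak and expression log10 fold-changes at each
    top-N cutoff; ``n_genes`` counts the genes contributing at each N."""

    top_n: np.ndarray
    r: np.ndarray  # NaN where fewer than 3 genes contribute
    n_genes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"top_n": self.top_n, "pearson_r": self.r, "n_genes": self.n_genes}
        )


# ---------------------------------------------------------------------------
# synthetic truth


def _overlap_pairs(
    query: pd.DataFrame, subject: pd.DataFrame
) -> pd.DataFrame:
    """All-pairs interval overlaps between two coordinate frames.

    Returns query_idx, subject_idx and overlap length (bp, > 0) for every
    overlapping pair. Vectorized per chromosome over the subject set;
    peak sets at benchmark scale are small enough for the quadratic
    worst case.
    """
    out = []
    for chrom, qsub in query.groupby("chrom", sort=False):
        ssub = subject[subject["chrom"] == chrom]
        if ssub.empty:
            continue
        s_start = ssub["start"].to_numpy()
        s_end = ssub["end"].to_numpy()
        s_index = ssub.index.to_numpy()
        for qi, qs, qe in zip(
            qsub.index, qsub["start"].to_numpy(), qsub["end"].to_numpy()
        ):
            ov = np.minimum(qe, s_end) - np.maximum(qs, s_start)
            hits = np.nonzero(ov > 0)[0]
            out.extend((qi, s_index[h], int(ov[h])) for h in hits)
    return pd.DataFrame(
        out, columns=["query_idx", "subject_idx", "overlap"]
    )


def overlap_truth(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    truth_peaks: PeakSet,
    fdr_threshold: float = 0.05,
    criterion: str = "1bp",
) -> DetectionReport:
    """Score significant detected peaks against the synthetic truth.

    Parameters
    ----------
    detected
        Differential table with chrom/start/end and FDR columns.
    truth, truth_peaks
        Truth table (peak_id, label, category) aligned with the truth
        peak set.
    criterion
        ``"1bp"`` — a true peak is detected if any significant peak
        overlaps it by >= 1 bp; ``"frac25"`` — by >= 25% of the true
        peak's length. A significant peak overlapping no true
        differential peak under the criterion is a false positive. Each
        true peak is counted at most once.
    """
    if criterion not in ("1bp", "frac25"):
        raise ValueError(f"criterion must be '1bp' or 'frac25', got {criterion!r}")
    required = {"chrom", "start", "end", "FDR"}
    if not required.issubset(detected.columns):
        raise ValueError(f"detected table needs columns {sorted(required)}")
    if len(truth) != len(truth_peaks):
        raise ValueError("truth table and truth peaks differ in length")

    det_chroms = set(detected["chrom"].unique())
    if det_chroms and not det_chroms & truth_peaks.chroms:
        raise ValueError(
            "no chromosome shared between detected peaks and truth"
        )

    sig = detected[detected["FDR"] < fdr_threshold].reset_index(drop=True)
    truth = truth.reset_index(drop=True)
    tframe = truth_peaks.frame[["chrom", "start", "end"]].reset_index(drop=True)
    diff_mask = (truth["label"] == "differential").to_numpy()

    cats = truth.loc[diff_mask, "category"].astype(int)
    tp_per_category = {int(c): 0 for c in sorted(cats.unique())}
    if sig.empty:
        return DetectionReport(
            tp_per_category, 0, 0, criterion, fdr_threshold
        )

    pairs = _overlap_pairs(
        sig[["chrom", "start", "end"]], tframe
    )
    if criterion == "frac25":
        tlen = (
            tframe["end"].to_numpy() - tframe["start"].to_numpy()
        )[pairs["subject_idx"].to_numpy(dtype=int)] if len(pairs) else np.array([])
        pairs = pairs[pairs["overlap"].to_numpy() >= 0.25 * tlen] if len(pairs) else pairs

    diff_pairs = (
        pairs[diff_mask[pairs["subject_idx"].to_numpy(dtype=int)]]
        if len(pairs)
        else pairs
    )
    hit_truth = set(diff_pairs["subject_idx"].astype(int)) if len(diff_pairs) else set()
    for ti in hit_truth:
        tp_per_category[int(truth.loc[ti, "category"])] += 1
    fp_query = set(range(len(sig))) - (
        set(diff_pairs["query_idx"].astype(int)) if len(diff_pairs) else set()
    )
    return DetectionReport(
        tp_per_category=tp_per_category,
        false_positives=len(fp_query),
        n_significant=len(sig),
        criterion=criterion,
        fdr_threshold=fdr_threshold,
    )


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC over binary truth labels, sweeping the score threshold.

    ``labels`` is boolean (True = differential); higher scores should
    indicate differential. Tied scores move along the curve together;
    AUC is the trapezoidal area. Missing scores must be imputed by the
    caller (convention: the minimum observed score).
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("truth labels contain a single class")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # threshold boundaries: positions where the score changes
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [len(s_sorted) - 1]])
    tp = np.cumsum(l_sorted)[cut]
    fp = np.cumsum(~l_sorted)[cut]
    tpr = np.concatenate([[0.0], tp / labels.sum()])
    fpr = np.concatenate([[0.0], fp / (~labels).sum()])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# expression correlation


def read_gene_table(path) -> pd.DataFrame:
    """TSV of gene_id, chrom, tss, strand (header optional)."""
    genes = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, comment="#")
    expected = ["gene_id", "chrom", "tss", "strand"]
    if list(genes.columns[:4]) != expected:
        genes = pd.read_csv(
            path, sep="\t", header=None, names=expected,
            dtype={0: str, 1: str}, comment="#",
        )
    genes["tss"] = genes["tss"].astype(np.int64)
    if (genes["tss"] < 0).any():
        raise ValueError("negative TSS coordinate")
    if genes["gene_id"].duplicated().any():
        dup = genes["gene_id"][genes["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r}")
    return genes


def read_expression_table(path) -> pd.Series:
    """TSV of gene_id and either log10_fc or fc; returns log10 fold-change."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    if "log10_fc" in frame.columns:
        values = frame["log10_fc"].astype(float)
    elif "fc" in frame.columns:
        values = np.log10(frame["fc"].astype(float))
    else:
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["gene_id", "log10_fc"],
            dtype={0: str}, comment="#",
        )
        values = frame["log10_fc"].astype(float)
    return pd.Series(values.to_numpy(), index=frame["gene_id"].to_numpy())


def annotate_nearest_gene(
    peaks: PeakSet, genes: pd.DataFrame
) -> pd.Series:
    """Assign each peak the gene whose TSS is nearest its midpoint.

    Distance is 0 when the TSS lies inside the peak. Ties go to the
    lexicographically smallest gene_id. Peaks on chromosomes without
    genes map to NA (excluded downstream).
    """
    if genes.empty:
        raise ValueError("gene table is empty")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        sub = sub.sort_values(["tss", "gene_id"], kind="stable")
        by_chrom[chrom] = (
            sub["tss"].to_numpy(),
            sub["gene_id"].to_numpy(dtype=object),
        )
    out = []
    for row in peaks.frame.itertuples(index=False):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            out.append(pd.NA)
            continue
        tss, ids = entry
        lo = bisect.bisect_left(tss, row.start)
        hi = bisect.bisect_left(tss, row.end)
        if hi > lo:  # TSS inside the peak: distance 0
            out.append(min(ids[lo:hi]))
            continue
        mid = (row.start + row.end) // 2
        pos = np.searchsorted(tss, mid)
        cand = []
        for p in (pos - 1, pos):
            if 0 <= p < len(tss):
                cand.append((abs(int(tss[p]) - mid), int(tss[p])))
        best = min(d for d, _ in cand)
        best_ids = [
            ids[i]
            for d, t in cand
            if d == best
            for i in np.nonzero(tss == t)[0]
        ]
        out.append(min(best_ids))
    return pd.Series(out, index=peaks.peak_ids, name="gene_id")


def fc_correlation(
    ranked_table: pd.DataFrame,
    annotation: pd.Series,
    expression_log10_fc: pd.Series,
    grid_step: int = 100,
    max_n: int = 2000,
) -> CorrelationCurve:
    """Pearson correlation of peak vs expression log10 fold-change over
    increasing top-N cutoffs (N = grid_step, 2*grid_step, ..., max_n).

    ``ranked_table`` must be sorted most significant first (by FDR) and
    carry feature_id and log2FC columns. When several top-N peaks
    annotate to the same gene, their log10 fold-changes are averaged.
    Cutoffs with fewer than 3 contributing genes report r = NaN.
    """
    if "log2FC" not in ranked_table.columns:
        raise ValueError("ranked table needs a log2FC column")
    peak_log10 = ranked_table["log2FC"].to_numpy(dtype=float) * np.log10(2.0)
    gene_ids = annotation.reindex(
        ranked_table["feature_id"].to_numpy(dtype=object)
    ).to_numpy(dtype=object)

    grid = np.arange(grid_step, max_n + 1, grid_step)
    r_vals = np.full(len(grid), np.nan)
    n_genes = np.zeros(len(grid), dtype=np.int64)
    for gi, n in enumerate(grid):
        sub = pd.DataFrame(
            {
                "gene_id": gene_ids[:n],
                "peak_log10_fc": peak_log10[:n],
            }
        ).dropna(subset=["gene_id"])
        per_gene = sub.groupby("gene_id", sort=True)["peak_log10_fc"].mean()
        expr = expression_log10_fc.reindex(per_gene.index)
        keep = expr.notna()
        per_gene, expr = per_gene[keep], expr[keep]
        n_genes[gi] = len(per_gene)
        if len(per_gene) >= 3:
            r_vals[gi] = sps.pearsonr(
                per_gene.to_numpy(), expr.to_numpy()
            ).statistic
    return CorrelationCurve(top_n=grid, r=r_vals, n_genes=n_genes)
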