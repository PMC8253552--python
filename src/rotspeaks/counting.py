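"""Read/fragment counting over candidate peaks from coordinate-sorted BAMs.

Fragment mode mirrors paired-end ATAC-seq counting: each properly paired
fragment (leftmost mate start to rightmost mate end, from TLEN) is counted
once per peak it overlaps by at least 1 bp. Read mode counts each passing
alignment once per overlapping peak. Strand is ignored — accessibility and
occupancy signals are strandless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .matrix import DataMatrix
from .peaks import PeakSet

__all__ = ["CountMatrix", "count_reads"]

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Peak x sample matrix of integer read (or fragment) counts."""

    peaks: PeakSet
    counts: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.counts.shape != (len(self.peaks), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.peaks)} peaks x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers before normalization")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_data_matrix(self) -> DataMatrix:
        return DataMatrix(
            values=self.counts.astype(float),
            feature_ids=self.peaks.peak_ids,
            sample_ids=self.sample_ids,
        )

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(
            self.counts, index=self.peaks.peak_ids, columns=self.sample_ids
        )
        frame.index.name = "peak_id"
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        ids = frame.index.astype(str)
        coords = ids.str.extract(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")
        if coords.isna().any().any():
            bad = ids[coords.isna().any(axis=1)][0]
            raise ValueError(
                f"peak id {bad!r} is not of the form chrom:start-end"
            )
        peaks = PeakSet(
            pd.DataFrame(
                {
                    "chrom": coords["chrom"].to_numpy(),
                    "start": coords["start"].astype(np.int64).to_numpy(),
                    "end": coords["end"].astype(np.int64).to_numpy(),
                }
            )
        )
        # PeakSet sorts; reorder the counts identically
        order = (
            pd.DataFrame(
                {
                    "chrom": coords["chrom"].to_numpy(),
                    "start": coords["start"].astype(np.int64).to_numpy(),
                    "end": coords["end"].astype(np.int64).to_numpy(),
                }
            )
            .sort_values(["chrom", "start", "end"], kind="stable")
            .index.to_numpy()
        )
        counts = frame.to_numpy()
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError(f"{path}: counts must be integers")
            counts = counts.astype(np.int64)
        return cls(
            peaks=peaks,
            counts=counts[order],
            sample_ids=frame.columns.to_numpy(dtype=object),
        )


def _passes(read: pysam.AlignedSegment, mapq: int, keep_duplicates: bool) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.is_qcfail:
        return False
    if not keep_duplicates and read.is_duplicate:
        return False
    return read.mapping_quality >= mapq


def _peak_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row_idx, row in enumerate(peaks.frame.itertuples(index=False)):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row_idx
        )
    return trees


def _count_one_sample(
    bam_path,
    trees: dict[str, IntervalTree],
    n_peaks: int,
    mode: str,
    mapq: int,
    keep_duplicates: bool,
) -> np.ndarray:
    counts = np.zeros(n_peaks, dtype=np.int64)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path}: BAM index (.bai) is missing")
        bam_contigs = set(bam.references)
        missing = set(trees) - bam_contigs
        if missing:
            logger.warning(
                "%s: contigs %s absent from BAM header; their peaks get "
                "zero counts", bam_path, sorted(missing),
            )
        for read in bam.fetch(until_eof=False):
            if not _passes(read, mapq, keep_duplicates):
                continue
            chrom = read.reference_name
            tree = trees.get(chrom)
            if tree is None:
                continue
            if mode == "fragment":
                # count each template once, at its leftmost mate
                if not read.is_proper_pair or read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
            else:
                start = read.reference_start
                end = read.reference_end
                if end is None or end <= start:
                    continue
            for hit in tree.overlap(start, end):
                counts[hit.data] += 1
    return counts


def count_reads(
    peaks: PeakSet,
    alignments: dict[str, str],
    mode: str = "fragment",
    mapq: int = 15,
    keep_duplicates: bool = False,
) -> CountMatrix:
    """Count reads or fragments per peak for every sample.

    Parameters
    ----------
    peaks
        Candidate peaks (need not be disjoint; a fragment overlapping two
        peaks increments both).
    alignments
        Mapping of sample id to coordinate-sorted, indexed BAM path.
    mode
        ``"fragment"`` counts each properly paired template once per
        overlapping peak; ``"read"`` counts individual alignments.
    mapq
        Minimum mapping quality; alignments below it are discarded.
    """
    if mode not in ("fragment", "read"):
        raise ValueError(f"mode must be 'fragment' or 'read', got {mode!r}")
    if not alignments:
        raise ValueError("no alignment files given")
    trees = _peak_trees(peaks)
    sample_ids = list(alignments)
    counts = np.column_stack(
        [
            _count_one_sample(
                alignments[s], trees, len(peaks), mode, mapq, keep_duplicates
            )
            for s in sample_ids
        ]
    )
    return CountMatrix(
        peaks=peaks,
        counts=counts,
        sample_ids=np.array(sample_ids, dtype=object),
    )
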