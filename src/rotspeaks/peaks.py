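"""Peak intervals: reading BED/narrowPeak calls and building the merged
candidate peak list.

Coordinates are 0-based half-open [start, end) throughout, the BED
convention; narrowPeak is treated as BED6+4.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "read_peaks",
    "merge_candidate_peaks",
]

_NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signal_value", "p_value", "q_value", "summit",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end <= start in {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class PeakSet:
    """An ordered collection of intervals, sorted by (chrom, start, end).

    Backed by a pandas DataFrame with at least chrom/start/end columns;
    extra columns (narrowPeak scores etc.) ride along.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required.issubset(frame.columns):
            raise ValueError(f"PeakSet frame needs columns {sorted(required)}")
        frame = frame.copy()
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
        if (frame["start"] < 0).any():
            raise ValueError("negative start coordinate")
        if (frame["end"] <= frame["start"]).any():
            i = frame.index[(frame["end"] <= frame["start"])][0]
            row = frame.loc[i]
            raise ValueError(
                f"end <= start at {row['chrom']}:{row['start']}-{row['end']}"
            )
        frame = frame.sort_values(
            ["chrom", "start", "end"], kind="stable"
        ).reset_index(drop=True)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        has_name = "name" in self.frame.columns
        has_score = "score" in self.frame.columns
        for row in self.frame.itertuples(index=False):
            yield GenomicInterval(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                name=getattr(row, "name", None) if has_name else None,
                score=getattr(row, "score", None) if has_score else None,
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        a = self.frame[["chrom", "start", "end"]]
        b = other.frame[["chrom", "start", "end"]]
        return a.equals(b)

    @property
    def peak_ids(self) -> np.ndarray:
        f = self.frame
        return (
            f["chrom"].astype(str) + ":" + f["start"].astype(str)
            + "-" + f["end"].astype(str)
        ).to_numpy(dtype=object)

    @property
    def chroms(self) -> set[str]:
        return set(self.frame["chrom"].unique())

    def total_bases(self) -> int:
        """Bases covered, counting overlapping intervals multiply."""
        return int((self.frame["end"] - self.frame["start"]).sum())

    def to_pyranges(self) -> pr.PyRanges:
        return pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": self.frame["chrom"],
                    "Start": self.frame["start"],
                    "End": self.frame["end"],
                }
            )
        )

    def to_bed(self, path, scores: np.ndarray | None = None) -> None:
        """Write BED; optional per-peak score column (4th+5th columns)."""
        out = self.frame[["chrom", "start", "end"]].copy()
        out["name"] = self.peak_ids
        if scores is not None:
            out["score"] = scores
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_intervals(cls, intervals) -> "PeakSet":
        rows = [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for iv in intervals
        ]
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _sniff_format(path: Path) -> str:
    return "narrowPeak" if path.suffix.lower() == ".narrowpeak" else "bed"


def read_peaks(path, format: str | None = None) -> PeakSet:
    """Read a BED (3-6 columns) or narrowPeak (10 columns) peak file.

    Malformed lines raise with the offending line number; output is
    sorted by (chrom, start, end).
    """
    path = Path(path)
    if format is None:
        format = _sniff_format(path)
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if format == "narrowPeak" and len(fields) != 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak requires 10 fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            row = {"chrom": fields[0], "start": start, "end": end}
            if format == "narrowPeak":
                row.update(dict(zip(_NARROWPEAK_COLS[3:], fields[3:])))
            else:
                if len(fields) > 3:
                    row["name"] = fields[3]
                if len(fields) > 4:
                    row["score"] = fields[4]
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no intervals found")
    return PeakSet(pd.DataFrame(rows))


def merge_candidate_peaks(peaksets: list[PeakSet]) -> PeakSet:
    """Union all peak sets and merge overlapping or book-ended intervals.

    This builds the candidate peak list for differential testing from
    per-sample or per-condition peak calls. Book-ended intervals
    ([a, b) + [b, c)) are merged, matching the bedtools default.
    """
    if not peaksets:
        raise ValueError("need at least one peak set")
    frames = [ps.frame[["chrom", "start", "end"]] for ps in peaksets]
    union = pd.concat(frames, ignore_index=True)
    if union.empty:
        raise ValueError("union of peak sets is empty")
    gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": union["chrom"],
                "Start": union["start"],
                "End": union["end"],
            }
        )
    )
    merged = gr.merge(slack=0).df  # slack=0 merges book-ended intervals
    return PeakSet(
        pd.DataFrame(
            {
                "chrom": merged["Chromosome"].astype(str),
                "start": merged["Start"],
                "end": merged["End"],
            }
        )
    )
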