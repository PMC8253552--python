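"""Input validation: existence, parseability, coordinate sanity and
cross-file sample-id consistency, reported without raising."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .matrix import GroupDesign
from .peaks import read_peaks

__all__ = ["Issue", "ValidationReport", "validate_inputs"]


@dataclass(frozen=True)
class Issue:
    path: str
    message: str

    def __str__(self) -> str:
        return f"{self.path}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, path, message: str) -> None:
        self.issues.append(Issue(str(path), message))

    def __str__(self) -> str:
        if self.ok:
            return "all inputs valid"
        return "\n".join(str(i) for i in self.issues)


def _check_peaks(report: ValidationReport, path, fmt: str | None) -> None:
    try:
        read_peaks(path, format=fmt)
    except (ValueError, OSError) as exc:
        report.add(path, str(exc))


def validate_inputs(
    peak_files: list[str] | None = None,
    peak_format: str | None = None,
    counts_path: str | None = None,
    design_path: str | None = None,
) -> ValidationReport:
    """Validate any combination of peak files, a count matrix and a
    design file; returns a report instead of raising.

    Checks: files exist and parse; interval coordinates are sane; every
    design sample is present in the count matrix and vice versa.
    """
    report = ValidationReport()
    for path in peak_files or []:
        if not Path(path).exists():
            report.add(path, "file not found")
        else:
            _check_peaks(report, path, peak_format)

    counts_samples: set[str] | None = None
    if counts_path is not None:
        if not Path(counts_path).exists():
            report.add(counts_path, "file not found")
        else:
            try:
                frame = pd.read_csv(counts_path, sep="\t", index_col=0)
                counts_samples = set(map(str, frame.columns))
                if frame.empty:
                    report.add(counts_path, "count matrix has no rows")
                elif (frame.select_dtypes("number") < 0).any().any():
                    report.add(counts_path, "negative counts present")
                if frame.index.duplicated().any():
                    dup = frame.index[frame.index.duplicated()][0]
                    report.add(counts_path, f"duplicate feature id {dup!r}")
            except (ValueError, OSError) as exc:
                report.add(counts_path, f"unreadable count matrix: {exc}")

    design: GroupDesign | None = None
    if design_path is not None:
        if not Path(design_path).exists():
            report.add(design_path, "file not found")
        else:
            try:
                design = GroupDesign.from_tsv(design_path)
            except (ValueError, OSError) as exc:
                report.add(design_path, str(exc))

    if design is not None and counts_samples is not None:
        for sample in design.sample_ids:
            if sample not in counts_samples:
                report.add(
                    design_path,
                    f"sample {sample!r} not present in count matrix",
                )
        for sample in sorted(counts_samples - set(design.sample_ids)):
            report.add(
                counts_path,
                f"sample {sample!r} has no condition in the design",
            )
    return report
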