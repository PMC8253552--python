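"""Count/data matrices and two-group sample designs.

The central in-memory objects of the package: a feature x sample matrix of
(normalized) read counts and a mapping of samples to exactly two biological
conditions. Both are thin, validated wrappers around numpy/pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DataMatrix", "GroupDesign"]


@dataclass
class DataMatrix:
    """A feature x sample matrix of non-negative real values.

    Rows are genomic features (peaks), columns are samples. Values are
    read counts, possibly normalized, hence real-valued.
    """

    values: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D feature x sample matrix")
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {n_feat} rows"
            )
        if len(self.sample_ids) != n_samp:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samp} columns"
            )
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("feature_ids must be unique")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("sample_ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain missing or non-finite entries")
        if (self.values < 0).any():
            raise ValueError("values must be non-negative")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DataMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            feature_ids=frame.index.to_numpy(dtype=object),
            sample_ids=frame.columns.to_numpy(dtype=object),
        )

    @classmethod
    def from_tsv(cls, path) -> "DataMatrix":
        """Read a TSV with a header row of sample ids and a first column of
        feature ids."""
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        return cls.from_frame(frame)

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "feature_id"
        frame.to_csv(path, sep="\t")


@dataclass
class GroupDesign:
    """Assignment of every sample to one of exactly two conditions.

    Condition order is the order of first appearance in ``assignment``;
    differences and fold-changes are oriented first-condition minus/over
    second-condition.
    """

    assignment: dict[str, str]
    _conditions: tuple[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for cond in self.assignment.values():
            if cond not in seen:
                seen.append(cond)
        if len(seen) != 2:
            raise ValueError(
                f"design must have exactly two conditions, got {seen}"
            )
        self._conditions = (seen[0], seen[1])
        for cond in self._conditions:
            n = sum(1 for c in self.assignment.values() if c == cond)
            if n < 2:
                raise ValueError(
                    f"condition {cond!r} has {n} sample(s); at least 2 required"
                )

    @property
    def conditions(self) -> tuple[str, str]:
        return self._conditions

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)

    def group_indices(
        self, sample_ids
    ) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of the two condition groups within ``sample_ids``.

        Raises if any design sample is missing from ``sample_ids``.
        """
        pos = {s: i for i, s in enumerate(sample_ids)}
        missing = [s for s in self.assignment if s not in pos]
        if missing:
            raise ValueError(f"samples in design but not in data: {missing}")
        ci, cj = self._conditions
        idx_i = np.array(
            [pos[s] for s, c in self.assignment.items() if c == ci], dtype=int
        )
        idx_j = np.array(
            [pos[s] for s, c in self.assignment.items() if c == cj], dtype=int
        )
        return idx_i, idx_j

    @classmethod
    def from_tsv(cls, path) -> "GroupDesign":
        """Read a two-column TSV: sample_id<TAB>condition (no header or with
        a ``sample_id`` header)."""
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if frame.shape[1] != 2:
            raise ValueError(
                f"design file {path} must have exactly 2 columns, "
                f"found {frame.shape[1]}"
            )
        if frame.iloc[0, 0] in ("sample_id", "sample"):
            frame = frame.iloc[1:]
        if frame.iloc[:, 0].duplicated().any():
            dup = frame.iloc[:, 0][frame.iloc[:, 0].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r} in design file {path}")
        return cls(dict(zip(frame.iloc[:, 0], frame.iloc[:, 1])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sample, cond in self.assignment.items():
                fh.write(f"{sample}\t{cond}\n")
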