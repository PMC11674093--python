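"""Plain-text I/O for expression matrices, label tables, selections and reports.

The canonical in-memory orientation is genes x samples (microarray
convention); downstream code derives samples-as-observations views from it.
Values are used as-is: no background correction or normalisation happens at
load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "DataFormatError",
    "read_expression",
    "read_labels",
    "align",
    "write_expression",
    "write_labels",
    "write_selection",
    "write_report",
    "read_report",
]


class DataFormatError(ValueError):
    """Raised for malformed, duplicated or non-numeric input tables."""


@dataclass
class ExpressionMatrix:
    """Continuous genes x samples expression table.

    ``values`` has shape (p, n) with ``gene_ids`` indexing rows and
    ``sample_ids`` indexing columns.  The expression scale is arbitrary
    (raw intensity or log-ratio); all finite continuous values are accepted.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p, n = self.values.shape
        if len(self.gene_ids) != p or len(self.sample_ids) != n:
            raise DataFormatError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes / {len(self.sample_ids)} samples"
            )
        if p < 1 or n < 2:
            raise DataFormatError(f"need p >= 1 genes and n >= 2 samples, got p={p}, n={n}")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise DataFormatError(f"duplicate {name} identifiers: {dup[:5]}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataFormatError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Return the sub-matrix for ``gene_ids``, in the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[idx])

    def restrict_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def samples_view(self) -> np.ndarray:
        """n x p array: samples as observations, genes as features."""
        return self.values.T


@dataclass
class LabelVector:
    """Per-sample class labels with a fixed class ordering.

    ``class_order`` fixes the categorical ordering used everywhere downstream
    (label coding, tie-breaks, confusion columns); by default it is the
    first-appearance order in the label file.
    """

    sample_ids: list[str]
    labels: list[str]
    class_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise DataFormatError("sample_ids and labels length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataFormatError("duplicate sample identifiers in labels")
        if any(not str(l).strip() for l in self.labels):
            raise DataFormatError("empty label encountered")
        if not self.class_order:
            seen: list[str] = []
            for l in self.labels:
                if l not in seen:
                    seen.append(l)
            self.class_order = seen
        if set(self.labels) - set(self.class_order):
            raise DataFormatError("labels outside class_order")
        if len(self.class_order) < 1:
            raise DataFormatError("at least one class required")

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def codes(self) -> np.ndarray:
        """Integer class codes in class_order (0-based)."""
        pos = {c: i for i, c in enumerate(self.class_order)}
        return np.array([pos[l] for l in self.labels], dtype=int)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.class_order}

    def subset(self, sample_ids: list[str]) -> "LabelVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        labels = [self.labels[pos[s]] for s in sample_ids]
        return LabelVector(list(sample_ids), labels, list(self.class_order))


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, orientation: str = "genes_as_rows") -> ExpressionMatrix:
    """Read a delimited expression table into canonical genes x samples form.

    The first column holds row identifiers and the header row holds column
    identifiers.  ``orientation`` must be explicit (``genes_as_rows`` or
    ``samples_as_rows``); it is never guessed from the file.
    """
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise DataFormatError(f"{path}: empty table")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise DataFormatError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if orientation == "samples_as_rows":
        numeric = numeric.T
    return ExpressionMatrix(
        [str(g) for g in numeric.index],
        [str(s) for s in numeric.columns],
        numeric.values,
    )


def read_labels(path: str | Path) -> LabelVector:
    """Read a two-column (sample_id, label) table with header."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected two columns (sample_id, label)")
    if df.empty:
        raise DataFormatError(f"{path}: empty label table")
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    labels = [("" if pd.isna(l) else str(l)) for l in df.iloc[:, 1]]
    return LabelVector(sample_ids, labels)


def align(X: ExpressionMatrix, y: LabelVector) -> tuple[ExpressionMatrix, LabelVector]:
    """Check that X and y cover the same samples; reorder y to X's order."""
    if set(X.sample_ids) != set(y.sample_ids):
        only_y = sorted(set(y.sample_ids) - set(X.sample_ids))
        only_x = sorted(set(X.sample_ids) - set(y.sample_ids))
        raise DataFormatError(
            f"sample mismatch between matrix and labels: "
            f"labels-only={only_y[:5]}, matrix-only={only_x[:5]}"
        )
    return X, y.subset(X.sample_ids)


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def write_labels(y: LabelVector, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": y.sample_ids, "label": y.labels}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_selection(sel, path: str | Path) -> None:
    """Write a consensus panel as TSV: gene_id, votes, aggregate_score, rank."""
    path = Path(path)
    rows = [
        {
            "gene_id": g,
            "votes": sel.votes[g],
            "aggregate_score": f"{sel.aggregate_rank[g]:.6f}",
            "rank": r + 1,
        }
        for r, g in enumerate(sel.gene_ids)
    ]
    pd.DataFrame(rows, columns=["gene_id", "votes", "aggregate_score", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def write_report(report: dict, path: str | Path) -> None:
    """Write a structured (JSON) evaluation report."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
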