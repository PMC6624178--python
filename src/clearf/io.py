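"""Delimited-text readers and writers.

One dataset format: samples as rows, a header of feature names plus one
label column, tab- or comma-separated. Score tables and cross-validation
reports are written as plain TSV/CSV so they diff cleanly and round-trip
through spreadsheets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CVReport, FeatureScoreTable, LabeledDataset, validate_dataset
from .exceptions import IOFormatError

__all__ = [
    "DatasetFileDialect",
    "read_dataset",
    "write_dataset",
    "write_scores",
    "write_cv_report",
]

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class DatasetFileDialect:
    """Dialect of a dataset file: delimiter and label column name."""

    delimiter: str = "\t"
    label_column: str = "label"


def read_dataset(path, dialect: DatasetFileDialect | None = None) -> LabeledDataset:
    """Read and validate a delimited dataset (samples as rows).

    Raises
    ------
    IOFormatError
        ``"dialect-error"`` if the label column is missing;
        ``"parse-error"`` naming the first offending cell if a feature
        value is not numeric.
    """
    dialect = dialect or DatasetFileDialect()
    df = pd.read_csv(path, sep=dialect.delimiter)
    if dialect.label_column not in df.columns:
        raise IOFormatError(
            "dialect-error",
            f"label column {dialect.label_column!r} not in header "
            f"{list(df.columns)}",
        )
    y = df[dialect.label_column].astype(str).to_numpy()
    feats = df.drop(columns=[dialect.label_column])
    for col in feats.columns:
        numeric = pd.to_numeric(feats[col], errors="coerce")
        bad = numeric.isna() & feats[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise IOFormatError(
                "parse-error",
                f"cell at row {row}, column {col!r} is not numeric: "
                f"{feats[col].iloc[row]!r}",
            )
        feats[col] = numeric
    d = LabeledDataset(
        X=feats.to_numpy(dtype=float),
        y=y,
        feature_names=[str(c) for c in feats.columns],
    )
    return validate_dataset(d)


def write_dataset(d: LabeledDataset, path, dialect: DatasetFileDialect | None = None) -> None:
    """Write a dataset in the same dialect :func:`read_dataset` accepts."""
    dialect = dialect or DatasetFileDialect()
    df = pd.DataFrame(d.X, columns=d.feature_names)
    df.insert(len(df.columns), dialect.label_column, d.y)
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format=_FLOAT_FMT)


def write_scores(table: FeatureScoreTable, path, delimiter: str = "\t") -> None:
    """Write a score table sorted by rank: feature, score, rank."""
    order = np.argsort(table.ranks)
    df = pd.DataFrame(
        {
            "feature": [table.feature_names[j] for j in order],
            "score": table.scores[order],
            "rank": table.ranks[order],
        }
    )
    df.to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FMT)


def write_cv_report(report: CVReport, path, delimiter: str = "\t") -> None:
    """Write per-fold accuracies (fold, feature_count, accuracy, selected_k)
    followed by a summary table (feature_count, mean_accuracy, sd) to a
    sibling file with suffix ``.summary`` appended to the stem."""
    rows = []
    for i in range(report.fold_accuracies.shape[0]):
        for j, f in enumerate(report.feature_counts):
            rows.append(
                {
                    "fold": i,
                    "feature_count": f,
                    "accuracy": report.fold_accuracies[i, j],
                    "selected_k": report.selected_component_sizes[i],
                }
            )
    pd.DataFrame(rows).to_csv(
        path, sep=delimiter, index=False, float_format=_FLOAT_FMT
    )
    summary = pd.DataFrame(
        report.summary(), columns=["feature_count", "mean_accuracy", "sd"]
    )
    p = Path(path)
    summary.to_csv(
        p.with_name(p.stem + ".summary" + p.suffix),
        sep=delimiter,
        index=False,
        float_format=_FLOAT_FMT,
    )
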