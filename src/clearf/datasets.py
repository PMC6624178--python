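"""Core in-memory data model.

A :class:`LabeledDataset` is a dense samples-by-features matrix with one
categorical class label per sample, the shape shared by bulk expression
matrices, SNP count tables and similar omics inputs. Result containers for
reconstruction errors, feature scores and cross-validation reports live here
too, so that every other module can exchange plain, validated values.

Class labels are opaque categorical values; wherever a deterministic class
order is needed the sorted order of the label strings is used. Internal
indexing is 0-based; user-facing ranks are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "LabeledDataset",
    "ReconstructionResult",
    "FeatureScoreTable",
    "CVReport",
    "validate_dataset",
]


@dataclass
class LabeledDataset:
    """Samples × features matrix with per-sample class labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Numeric measurements (e.g. expression values). Must be finite.
    y : ndarray of shape (n_samples,)
        Class label per sample, any hashable values; compared as strings
        for ordering purposes.
    feature_names : sequence of str
        Unique identifier per feature column.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValidationError("bad-shape", "X must be 2-dimensional")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        self.feature_names = [str(n) for n in self.feature_names]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list:
        """Labels in deterministic (string-sorted) order."""
        return sorted(set(self.y.tolist()), key=str)

    @property
    def class_counts(self) -> dict:
        return {c: int((self.y == c).sum()) for c in self.classes}


def validate_dataset(d: LabeledDataset) -> LabeledDataset:
    """Check all :class:`LabeledDataset` invariants, returning ``d`` unchanged.

    Raises
    ------
    ValidationError
        ``"missing-data"`` for NaN/inf cells, ``"degenerate-labels"`` for an
        empty label set or label/matrix length mismatch,
        ``"duplicate-feature"`` for repeated feature names.
    """
    if d.n_samples < 2:
        raise ValidationError("degenerate-labels", "need at least 2 samples")
    if d.n_features < 1:
        raise ValidationError("degenerate-labels", "need at least 1 feature")
    if d.y.shape[0] != d.n_samples:
        raise ValidationError(
            "degenerate-labels",
            f"{d.y.shape[0]} labels for {d.n_samples} samples",
        )
    if len(d.classes) < 1:
        raise ValidationError("degenerate-labels", "empty label set")
    if not np.isfinite(d.X).all():
        bad = np.argwhere(~np.isfinite(d.X))[0]
        raise ValidationError(
            "missing-data",
            f"non-finite value at sample {bad[0]}, feature {bad[1]} "
            "(remove features with missing data upstream)",
        )
    if len(d.feature_names) != d.n_features:
        raise ValidationError(
            "duplicate-feature",
            f"{len(d.feature_names)} names for {d.n_features} features",
        )
    if len(set(d.feature_names)) != d.n_features:
        seen, dup = set(), None
        for n in d.feature_names:
            if n in seen:
                dup = n
                break
            seen.add(n)
        raise ValidationError("duplicate-feature", f"feature name {dup!r} repeated")
    return d


@dataclass
class ReconstructionResult:
    """Per-feature reconstruction error of one (sub)dataset.

    ``total_error`` always equals the sum of ``per_feature_error`` (for
    aggregation ``"sum"`` this is the total squared error; for ``"mean"`` it
    is the sum of per-feature mean squared errors).
    """

    per_feature_error: np.ndarray
    total_error: float
    n_samples_used: int
    aggregation: str


@dataclass
class FeatureScoreTable:
    """ClearF scores with a deterministic descending ranking.

    ``ranks[j]`` is the 1-based rank of feature ``j``; rank 1 is the highest
    score, ties broken by ascending feature index.
    """

    feature_names: list[str]
    scores: np.ndarray
    ranks: np.ndarray

    def top(self, k: int) -> list[int]:
        """Indices of the ``k`` best-ranked features, best first."""
        order = np.argsort(self.ranks)
        return order[:k].tolist()


@dataclass
class CVReport:
    """Accuracy of the cross-validated feature-count benchmark.

    ``fold_accuracies`` has shape (n_folds, len(feature_counts));
    ``mean_accuracy`` is its column mean; ``selected_component_sizes`` holds
    the embedding size chosen on each fold's training data.
    """

    feature_counts: list[int]
    fold_accuracies: np.ndarray
    mean_accuracy: np.ndarray
    selected_component_sizes: list[int]
    method: str

    def summary(self):
        """(feature_count, mean, sd) rows as a list of tuples."""
        sd = self.fold_accuracies.std(axis=0, ddof=1)
        return [
            (f, float(m), float(s))
            for f, m, s in zip(self.feature_counts, self.mean_accuracy, sd)
        ]
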