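"""Component-size search and the cross-validated feature-count benchmark.

The embedding size k is the method's one substantive hyperparameter. It is
chosen by a small greedy search anchored on the smallest class: with Cmin
the sample count of the smallest class in the training data, the candidates
are {1, Cmin/4, Cmin/2, 3*Cmin/4, Cmin} (rounded, floored at 1,
deduplicated). The training data is split into three equal-sized subsets —
two for fitting, one for validation — and the candidate whose top-ranked
features give the best validation accuracy with an RBF-kernel SVM wins;
ties go to the smaller size.

The benchmark harness runs stratified 10-fold cross-validation: per fold,
scores are computed on the training split only, the top-f features (f = 5,
10, ..., 50 by default) are handed to the SVM, and accuracy is measured on
the held-out fold. Feature selection never sees the test fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .datasets import CVReport, LabeledDataset, validate_dataset
from .exceptions import ValidationError
from .scoring import ClearF, ScoreConfig

__all__ = [
    "SelectionConfig",
    "candidate_component_sizes",
    "select_component_size",
    "cross_validate",
]


@dataclass
class SelectionConfig:
    """Benchmark protocol parameters.

    ``svm_c`` / ``svm_gamma`` are the RBF-SVM hyperparameters, fixed at the
    conventional defaults (C=1, gamma="scale") for reproducibility.
    ``inner_rotation`` rotates the inner validation subset over all three
    thirds and averages; off by default (a single split).
    """

    feature_counts: tuple[int, ...] = tuple(range(5, 55, 5))
    n_folds: int = 10
    seed: int = 0
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    inner_rotation: bool = False

    def __post_init__(self):
        fc = tuple(int(f) for f in self.feature_counts)
        if not fc or any(f < 1 for f in fc) or any(
            b <= a for a, b in zip(fc, fc[1:])
        ):
            raise ValidationError(
                "bad-feature-counts",
                "feature_counts must be strictly increasing positive integers",
            )
        self.feature_counts = fc


def candidate_component_sizes(c_min: int) -> list[int]:
    """Candidate embedding sizes {1, Cmin/4, Cmin/2, 3Cmin/4, Cmin}.

    Fractions are rounded to the nearest integer (half away from zero) and
    floored at 1; duplicates are dropped, ascending order preserved.
    """
    if c_min < 1:
        raise ValidationError("invalid-cmin", f"c_min must be >= 1, got {c_min}")
    raw = [1] + [max(1, int(np.floor(c_min * q + 0.5))) for q in (0.25, 0.5, 0.75)] + [c_min]
    out: list[int] = []
    for k in sorted(raw):
        if not out or k != out[-1]:
            out.append(k)
    return out


def _svm(cfg: SelectionConfig) -> SVC:
    return SVC(kernel="rbf", C=cfg.svm_c, gamma=cfg.svm_gamma)


def _selector(score_cfg: ScoreConfig, k: int) -> ClearF:
    return ClearF(
        method=score_cfg.embedding.method,
        n_components=k,
        aggregation=score_cfg.aggregation,
        standardize=score_cfg.standardize,
        poly_degree=score_cfg.embedding.poly_degree,
        rbf_gamma=score_cfg.embedding.rbf_gamma,
        preimage_ridge=score_cfg.embedding.preimage_ridge,
    )


def _inner_splits(y: np.ndarray, cfg: SelectionConfig, rotate: bool):
    """Indices of (fit, validation) pairs for the inner 3-subset split."""
    idx = np.arange(len(y))
    _, counts = np.unique(y, return_counts=True)
    stratify_ok = counts.min() >= 3
    if rotate and stratify_ok:
        kf = StratifiedKFold(n_splits=3, shuffle=True, random_state=cfg.seed)
        return [(tr, va) for tr, va in kf.split(idx, y)]
    stratify = y if stratify_ok else None
    tr, va = train_test_split(
        idx, test_size=1 / 3, random_state=cfg.seed, stratify=stratify
    )
    return [(tr, va)]


def select_component_size(
    train: LabeledDataset,
    cfg: SelectionConfig,
    score_cfg: ScoreConfig,
    n_features_to_keep: int,
) -> int:
    """Pick the embedding size with the best inner validation accuracy.

    Cmin is the smallest class count in ``train``. Each candidate size is
    scored on two thirds of the training data, the top
    ``n_features_to_keep`` features feed an RBF-SVM, and accuracy is read
    on the remaining third. Ties break toward the smaller size; a single
    candidate (Cmin = 1) is returned without any evaluation.
    """
    train = validate_dataset(train)
    c_min = min(train.class_counts.values())
    candidates = candidate_component_sizes(c_min)
    if len(candidates) == 1:
        return candidates[0]
    n_keep = min(n_features_to_keep, train.n_features)
    splits = _inner_splits(train.y, cfg, cfg.inner_rotation)
    best_k, best_acc = None, -1.0
    for k in candidates:
        accs = []
        for tr, va in splits:
            sel = _selector(score_cfg, k).fit(train.X[tr], train.y[tr])
            top = np.flatnonzero(sel.ranking_ <= n_keep)
            clf = _svm(cfg).fit(train.X[np.ix_(tr, top)], train.y[tr])
            accs.append(clf.score(train.X[np.ix_(va, top)], train.y[va]))
        acc = float(np.mean(accs))
        if acc > best_acc:  # strict: ties keep the earlier (smaller) size
            best_k, best_acc = k, acc
    return best_k


def cross_validate(
    d: LabeledDataset, cfg: SelectionConfig, score_cfg: ScoreConfig | None = None
) -> CVReport:
    """Cross-validated accuracy over a grid of selected-feature counts.

    Per fold: the component size is selected on the training split (inner
    split, largest feature count of the grid), features are scored and
    ranked on the training split only, and an RBF-SVM trained on the top-f
    features is evaluated on the held-out fold for every f in
    ``cfg.feature_counts``.
    """
    score_cfg = score_cfg or ScoreConfig()
    d = validate_dataset(d)
    if max(cfg.feature_counts) > d.n_features:
        raise ValidationError(
            "too-many-features",
            f"feature count {max(cfg.feature_counts)} exceeds "
            f"{d.n_features} available features",
        )
    if min(d.class_counts.values()) >= cfg.n_folds:
        folds = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
        ).split(d.X, d.y)
    else:
        warnings.warn(
            "smallest class has fewer samples than folds; using unstratified folds",
            stacklevel=2,
        )
        folds = KFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
        ).split(d.X)

    fold_acc = np.zeros((cfg.n_folds, len(cfg.feature_counts)))
    selected: list[int] = []
    for i, (tr, te) in enumerate(folds):
        train = LabeledDataset(
            X=d.X[tr], y=d.y[tr], feature_names=list(d.feature_names)
        )
        k = select_component_size(train, cfg, score_cfg, max(cfg.feature_counts))
        selected.append(k)
        sel = _selector(score_cfg, k).fit(train.X, train.y)
        for j, f in enumerate(cfg.feature_counts):
            top = np.flatnonzero(sel.ranking_ <= f)
            clf = _svm(cfg).fit(train.X[:, top], train.y)
            fold_acc[i, j] = clf.score(d.X[np.ix_(te, top)], d.y[te])
    return CVReport(
        feature_counts=list(cfg.feature_counts),
        fold_accuracies=fold_acc,
        mean_accuracy=fold_acc.mean(axis=0),
        selected_component_sizes=selected,
        method=(
            f"{score_cfg.embedding.method}"
            f"/{score_cfg.aggregation}"
            f"/standardize={score_cfg.standardize}"
        ),
    )
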