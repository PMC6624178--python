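"""Low-dimensional embedding with reconstruction back to input space.

The scoring method needs one primitive: embed a (sub)dataset into k
components and map it back to the original feature space, so that squared
residuals can be read off per feature. Three backends are supported:

* ``"linear-pca"`` — ordinary PCA; reconstruction is the rank-k expansion
  about the column means.
* ``"kernel-rbf"`` / ``"kernel-poly"`` — kernel PCA (RBF, or polynomial of
  degree 3). Kernel PCA has no exact inverse, so the pre-image is
  approximated by a ridge-regularized linear map from the embedded
  coordinates back to input space, fitted on the same data.

Each (sub)dataset is centered by its own column means before embedding.
Requested component counts that exceed what the data can support (small
class subsets) are capped silently; the cap is recorded in
``effective_components_``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, KernelPCA

from .exceptions import ValidationError

__all__ = [
    "EmbeddingSpec",
    "ReconstructingEmbedding",
    "fit_reconstruct",
    "total_squared_error",
]

_METHODS = ("linear-pca", "kernel-rbf", "kernel-poly")


@dataclass(frozen=True)
class EmbeddingSpec:
    """Configuration of an embedding backend.

    Parameters
    ----------
    method : {"linear-pca", "kernel-rbf", "kernel-poly"}
    n_components : int
        Requested number of components k (>= 1). The same k must be used
        for the whole dataset and every class subset when scoring.
    poly_degree : int, default 3
        Degree of the polynomial kernel.
    rbf_gamma : float or "auto", default "auto"
        RBF kernel width; "auto" uses 1 / (n_features * var(X)) of the data
        being fitted.
    preimage_ridge : float, default 1e-3
        Ridge regularization of the linear pre-image map (kernel methods).
    """

    method: str = "linear-pca"
    n_components: int = 1
    poly_degree: int = 3
    rbf_gamma: float | str = "auto"
    preimage_ridge: float = 1e-3

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValidationError(
                "bad-method", f"method must be one of {_METHODS}, got {self.method!r}"
            )
        if self.n_components < 1:
            raise ValidationError("bad-components", "n_components must be >= 1")
        if self.preimage_ridge < 0:
            raise ValidationError("bad-ridge", "preimage_ridge must be >= 0")
        if self.rbf_gamma != "auto" and not self.rbf_gamma > 0:
            raise ValidationError("bad-gamma", "rbf_gamma must be positive or 'auto'")


def _check_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("bad-shape", "X must be a 2-d matrix")
    if X.shape[0] < 2:
        raise ValidationError(
            "insufficient-samples", f"need >= 2 samples to embed, got {X.shape[0]}"
        )
    if not np.isfinite(X).all():
        raise ValidationError("non-finite-input", "X contains NaN or inf")
    return X


class ReconstructingEmbedding(TransformerMixin, BaseEstimator):
    """Embed data into k components and reconstruct it in feature space.

    A thin sklearn-style transformer over PCA / KernelPCA whose
    ``inverse_transform`` always lands back in the original feature space,
    including for kernel methods (via the ridge pre-image map).

    Attributes
    ----------
    effective_components_ : int
        k after capping at the feasible maximum for the fitted data.
    n_samples_fit_ : int
        Number of samples the embedding was fitted on.
    mean_ : ndarray of shape (n_features,)
        Column means used for centering.
    """

    def __init__(
        self,
        method: str = "linear-pca",
        n_components: int = 1,
        poly_degree: int = 3,
        rbf_gamma: float | str = "auto",
        preimage_ridge: float = 1e-3,
    ):
        self.method = method
        self.n_components = n_components
        self.poly_degree = poly_degree
        self.rbf_gamma = rbf_gamma
        self.preimage_ridge = preimage_ridge

    def _spec(self) -> EmbeddingSpec:
        return EmbeddingSpec(
            method=self.method,
            n_components=self.n_components,
            poly_degree=self.poly_degree,
            rbf_gamma=self.rbf_gamma,
            preimage_ridge=self.preimage_ridge,
        )

    def fit(self, X, y=None):
        spec = self._spec()
        X = _check_matrix(X)
        n, p = X.shape
        self.n_samples_fit_ = n
        self.n_features_in_ = p
        self.mean_ = X.mean(axis=0)
        k = spec.n_components
        if spec.method == "linear-pca":
            self.effective_components_ = max(1, min(k, n - 1, p))
            self._model = PCA(
                n_components=self.effective_components_, svd_solver="full"
            )
            self._model.fit(X)
        else:
            self.effective_components_ = max(1, min(k, n - 1))
            kernel = "rbf" if spec.method == "kernel-rbf" else "poly"
            if kernel == "rbf":
                gamma = (
                    1.0 / (p * X.var())
                    if spec.rbf_gamma == "auto"
                    else float(spec.rbf_gamma)
                )
            else:
                gamma = None  # sklearn default 1/p for the polynomial kernel
            self._model = KernelPCA(
                n_components=self.effective_components_,
                kernel=kernel,
                gamma=gamma,
                degree=spec.poly_degree,
                eigen_solver="dense",
            )
            Z = self._model.fit_transform(X)
            # ridge-regularized linear pre-image: Z -> centered X
            ZtZ = Z.T @ Z + spec.preimage_ridge * np.eye(Z.shape[1])
            self._preimage_W = np.linalg.solve(ZtZ, Z.T @ (X - self.mean_))
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return self._model.transform(X)

    def inverse_transform(self, Z):
        if self.method == "linear-pca":
            return self._model.inverse_transform(Z)
        return np.asarray(Z) @ self._preimage_W + self.mean_

    def reconstruct(self, X) -> np.ndarray:
        """Round-trip ``X`` through the embedding; same shape as ``X``."""
        return self.inverse_transform(self.transform(np.asarray(X, dtype=float)))


def fit_reconstruct(X, spec: EmbeddingSpec):
    """Fit ``spec`` on ``X`` and return ``(Xhat, fitted)``.

    ``Xhat`` has the same shape as ``X``: the rank-k PCA expansion for the
    linear method, the ridge pre-image estimate for kernel methods.
    """
    est = ReconstructingEmbedding(
        method=spec.method,
        n_components=spec.n_components,
        poly_degree=spec.poly_degree,
        rbf_gamma=spec.rbf_gamma,
        preimage_ridge=spec.preimage_ridge,
    ).fit(X)
    return est.reconstruct(X), est


def total_squared_error(X, Xhat) -> float:
    """Sum of squared residuals over all samples and features."""
    X = np.asarray(X, dtype=float)
    Xhat = np.asarray(Xhat, dtype=float)
    if X.shape != Xhat.shape:
        raise ValidationError(
            "shape-mismatch", f"shapes {X.shape} and {Xhat.shape} differ"
        )
    return float(((X - Xhat) ** 2).sum())
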