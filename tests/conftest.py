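import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("det")


def eig_pca_reconstruct(X, k):
    """Independent rank-k PCA reconstruction via an explicit eigen-decomposition
    of the sample covariance (oracle; no sklearn)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    Xc = X - mu
    C = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(C)
    top = V[:, np.argsort(w)[::-1][:k]]
    return Xc @ top @ top.T + mu


def brute_force_clearf(X, y, k, aggregation="sum"):
    """Independent ClearF scores: explicit eigen-PCA per subset, column-wise
    squared-residual aggregation, pooled minus summed class-wise."""
    X = np.asarray(X, dtype=float)

    def ferr(M):
        resid = (M - eig_pca_reconstruct(M, k)) ** 2
        return resid.sum(0) if aggregation == "sum" else resid.mean(0)

    total = ferr(X)
    for c in sorted(set(y.tolist()), key=str):
        total = total - ferr(X[np.asarray(y) == c])
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_dataset():
    from clearf import LabeledDataset

    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 4))
    X[:6, 0] += 3.0
    y = np.array(["a"] * 6 + ["b"] * 6)
    return LabeledDataset(X=X, y=y, feature_names=["g1", "g2", "g3", "g4"])
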