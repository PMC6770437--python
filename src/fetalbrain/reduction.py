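"""Principal component analysis for the high-dimensional feature subsets.

Thin SVD of the centred training matrix; components are ranked by explained
variance and sign-fixed so each component's largest-magnitude loading is
positive.  The Gabor-bearing subsets (2 and 6) must pass through here
before classification; the fit is always fold-local in cross-validation so
no test-fold statistics leak into the projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PCAModel:
    component_matrix: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray  # per-component, non-increasing
    column_means: np.ndarray
    n_components: int

    def save(self, path) -> None:
        np.savez(path, components=self.component_matrix,
                 explained_variance=self.explained_variance,
                 means=self.column_means)

    @classmethod
    def load(cls, path) -> "PCAModel":
        z = np.load(path)
        return cls(component_matrix=z["components"],
                   explained_variance=z["explained_variance"],
                   column_means=z["means"],
                   n_components=z["components"].shape[0])


def pca_fit(X: np.ndarray, n_components: int | None = None,
            variance_fraction: float = 0.95) -> PCAModel:
    """Fit PCA on training rows.

    Either a fixed component count or (default) the smallest count whose
    cumulative explained variance reaches ``variance_fraction``, capped at
    rows - 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components is not None and n_components > max_comp:
        raise ValueError(
            f"n_components {n_components} exceeds min(rows-1, cols) = {max_comp}")
    means = X.mean(axis=0)
    Xc = X - means
    # thin SVD: components are right singular vectors
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (n - 1)
    Vt, var = Vt[:max_comp], var[:max_comp]
    if n_components is None:
        total = var.sum()
        if total <= 0:
            k = 1
        else:
            cum = np.cumsum(var) / total
            k = int(np.searchsorted(cum, variance_fraction) + 1)
            k = min(k, max_comp)
    else:
        k = n_components
    comps = Vt[:k].copy()
    # sign convention: largest-|loading| entry of each component positive
    for row in comps:
        idx = int(np.argmax(np.abs(row)))
        if row[idx] < 0:
            row *= -1.0
    return PCAModel(component_matrix=comps, explained_variance=var[:k].copy(),
                    column_means=means, n_components=k)


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.column_means.size:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model "
            f"({model.column_means.size})")
    return (X - model.column_means) @ model.component_matrix.T


def pca_inverse_transform(model: PCAModel, Z: np.ndarray) -> np.ndarray:
    return np.asarray(Z) @ model.component_matrix + model.column_means


def total_variance(X: np.ndarray) -> float:
    """Sum of per-column sample variances (N-1 denominator)."""
    X = np.asarray(X, dtype=float)
    return float(np.sum(X.var(axis=0, ddof=1)))
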