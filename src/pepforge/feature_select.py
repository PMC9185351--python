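"""PCA feature pruning: center, covariance eigendecomposition, project.

The decomposition is computed through a thin SVD of the centered training
matrix, which yields exactly the eigenpairs of the sample covariance
(divisor Q-1, Q = number of training peptides) while staying tractable when
the fused feature space (8441 columns for all four encoders at lambda=1) is
far wider than the number of peptides.  Components beyond the matrix rank
carry eigenvalue zero and are not stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoders import FeatureMatrix

__all__ = ["PCAModel", "fit_pca", "transform_pca"]


@dataclass(frozen=True)
class PCAModel:
    """Fitted PCA: column means, descending eigenvalues, orthonormal
    eigenvectors (columns), and the retained dimension K."""

    mean: np.ndarray              # (P,)
    eigenvalues: np.ndarray       # (r,) non-increasing, r = rank bound
    components: np.ndarray        # (P, r) orthonormal columns
    retained_dim: int             # K
    n_samples: int
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        if np.any(self.eigenvalues < -1e-9):
            raise ValueError("eigenvalues must be non-negative")
        if not 1 <= self.retained_dim <= self.components.shape[1]:
            raise ValueError("retained dimension out of range")
        if self.retained_dim >= self.n_samples:
            raise ValueError("retained dimension must be below the number of samples")

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def cumulative_explained_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)

    def save_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# pepforge PCA model; K={self.retained_dim}; n_samples={self.n_samples}\n")
            fh.write("column\tmean\t" + "\t".join(f"V{j+1}" for j in range(self.components.shape[1])) + "\n")
            fh.write("eigenvalue\t\t" + "\t".join(repr(v) for v in self.eigenvalues) + "\n")
            for name, mu, row in zip(self.column_names, self.mean, self.components):
                fh.write(name + "\t" + repr(mu) + "\t" + "\t".join(repr(v) for v in row) + "\n")
        return path


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude loading positive (first such
    index on exact ties) so serialized models are reproducible."""
    flip = np.sign(components[np.argmax(np.abs(components), axis=0), np.arange(components.shape[1])])
    flip[flip == 0] = 1.0
    return components * flip


def fit_pca(train: FeatureMatrix, retention: float | None = 0.95, k: int | None = None) -> PCAModel:
    """Fit PCA on a training matrix.

    ``retention`` picks the smallest K whose cumulative explained variance
    reaches that fraction; an explicit ``k`` overrides it.  Either way K is
    clamped below the number of training samples and to the matrix rank.
    """
    X = train.values
    Q, P = X.shape
    if Q < 2:
        raise ValueError("PCA needs at least 2 training rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input contains non-finite entries")

    mean = X.mean(axis=0)
    centered = X - mean
    # thin SVD: eigenvalues of the (Q-1)-divisor covariance are s^2 / (Q-1)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (Q - 1)
    components = _fix_signs(vt.T)

    # numerical rank: discard directions with (near-)zero variance
    tol = eigenvalues[0] * max(Q, P) * np.finfo(float).eps if eigenvalues.size else 0.0
    rank = max(int(np.sum(eigenvalues > tol)), 1)
    eigenvalues = eigenvalues[:rank]
    components = components[:, :rank]

    k_max = min(rank, Q - 1)
    if k is not None:
        if k < 1:
            raise ValueError("explicit K must be positive")
        K = min(k, k_max)
    else:
        if retention is None or not 0.0 < retention <= 1.0:
            raise ValueError("retention must lie in (0, 1]")
        cum = np.cumsum(eigenvalues) / eigenvalues.sum()
        K = int(np.searchsorted(cum, retention - 1e-12) + 1)
        K = min(K, k_max)

    return PCAModel(
        mean=mean,
        eigenvalues=eigenvalues,
        components=components,
        retained_dim=K,
        n_samples=Q,
        column_names=train.column_names,
    )


def transform_pca(model: PCAModel, data: FeatureMatrix, k: int | None = None) -> FeatureMatrix:
    """Project rows onto the first K principal components."""
    K = model.retained_dim if k is None else k
    if not 1 <= K <= model.components.shape[1]:
        raise ValueError(f"K={K} out of range for a rank-{model.components.shape[1]} model")
    if data.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"data has {data.shape[1]} columns; model expects {model.mean.shape[0]}"
        )
    projected = (data.values - model.mean) @ model.components[:, :K]
    return FeatureMatrix(
        row_ids=data.row_ids,
        column_names=tuple(f"PC{j+1}" for j in range(K)),
        values=projected,
        encoder_tag=f"{data.encoder_tag}|pca(K={K})",
    )
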