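"""PCA over Procrustes-aligned shape coordinates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpa import ProcrustesResult


class PCAError(ValueError):
    pass


@dataclass
class ShapeSpace:
    """Mean shape + orthonormal PC basis over flattened (3k) coordinates."""

    mean_shape: np.ndarray       # (k, 3)
    basis: np.ndarray            # (d, 3k), rows orthonormal
    eigenvalues: np.ndarray      # (d,), non-increasing
    cumulative_variance: np.ndarray  # (d,), of the *retained* axes over total
    scores: np.ndarray           # (n, d)
    total_variance: float

    @property
    def d(self) -> int:
        return len(self.eigenvalues)

    @property
    def k(self) -> int:
        return len(self.mean_shape)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Scores of a centered-at-mean configuration (k, 3)."""
        diff = np.asarray(points, dtype=float).reshape(-1) - self.mean_shape.reshape(-1)
        return self.basis @ diff

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """(k, 3) shape from PC scores."""
        flat = self.mean_shape.reshape(-1) + np.asarray(scores, dtype=float) @ self.basis
        return flat.reshape(-1, 3)


def pca_shapes(aligned, cumulative_threshold: float = 0.95) -> ShapeSpace:
    """Shape PCA keeping the smallest dimension reaching the threshold.

    ``aligned`` is a :class:`ProcrustesResult` or an (n, k, 3) array of
    superimposed configurations.
    """
    if not 0.0 < cumulative_threshold <= 1.0:
        raise PCAError("cumulative_threshold must be in (0, 1]")
    if isinstance(aligned, ProcrustesResult):
        X = aligned.flat()
    else:
        X = np.asarray(aligned, dtype=float)
        X = X.reshape(len(X), -1)
    n = len(X)
    if n < 3:
        raise PCAError("need at least 3 specimens")
    mean_flat = X.mean(axis=0)
    Xc = X - mean_flat
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    total = float(eigvals.sum())
    nonzero = eigvals > max(1e-14 * (eigvals[0] if len(eigvals) else 1.0), 0.0)
    eigvals = eigvals[nonzero]
    Vt = Vt[nonzero]
    s = s[nonzero]
    if total <= 0:
        d = 0
    else:
        cum = np.cumsum(eigvals) / total
        d = int(np.searchsorted(cum, cumulative_threshold - 1e-12) + 1)
        d = min(d, len(eigvals))
    basis = Vt[:d]
    eig = eigvals[:d]
    scores = Xc @ basis.T
    cumvar = (np.cumsum(eig) / total) if total > 0 else np.zeros(d)
    return ShapeSpace(
        mean_shape=mean_flat.reshape(-1, 3),
        basis=basis,
        eigenvalues=eig,
        cumulative_variance=cumvar,
        scores=scores,
        total_variance=total,
    )
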