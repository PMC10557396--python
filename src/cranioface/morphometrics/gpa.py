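"""Generalized Procrustes analysis and Procrustes distances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..meshkit.landmarks import Configuration


class ProcrustesError(ValueError):
    pass


def _stack(configs) -> np.ndarray:
    arrs = []
    for c in configs:
        pts = c.points if isinstance(c, Configuration) else np.asarray(c, dtype=float)
        arrs.append(pts.reshape(-1, 3))
    ks = {len(a) for a in arrs}
    if len(ks) != 1:
        raise ProcrustesError(f"configurations have differing landmark counts: {ks}")
    return np.stack(arrs)


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances to the centroid."""
    c = points - points.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R minimizing ||A @ R.T - B|| for centered configurations."""
    H = B.T @ A
    U, _, Vt = np.linalg.svd(H)
    sgn = np.ones(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        sgn[-1] = -1.0
    return U @ np.diag(sgn) @ Vt


@dataclass
class ProcrustesResult:
    aligned: np.ndarray            # (n, k, 3) superimposed configurations
    mean_shape: np.ndarray         # (k, 3)
    centroid_sizes: np.ndarray     # (n,) original sizes
    distances: np.ndarray          # (n,) Procrustes distance to the mean
    with_scaling: bool

    @property
    def n(self) -> int:
        return len(self.aligned)

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """(n, 3k) row-per-specimen matrix of aligned coordinates."""
        return self.aligned.reshape(self.n, -1)


def gpa(configs, with_scaling: bool = True, tol: float = 1e-12,
        max_iter: int = 200) -> ProcrustesResult:
    """Iterative generalized Procrustes superimposition.

    With scaling on, every aligned configuration has unit centroid size and
    the result is invariant (to numerical tolerance) under similarity
    transforms of any input; without scaling, under rigid motions only.
    """
    X = _stack(configs)
    n = len(X)
    if n < 2:
        raise ProcrustesError("need at least 2 configurations")
    sizes = np.array([centroid_size(x) for x in X])
    if np.any(sizes < 1e-12):
        raise ProcrustesError("degenerate zero-size configuration")
    X = X - X.mean(axis=1, keepdims=True)
    if with_scaling:
        X = X / sizes[:, None, None]
    mean = X[0].copy()
    for _ in range(max_iter):
        for i in range(n):
            R = _optimal_rotation(X[i], mean)
            X[i] = X[i] @ R.T
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        if with_scaling:
            ms = centroid_size(new_mean)
            if ms > 0:
                new_mean = new_mean / ms
        change = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if change < tol:
            break
    # final rotation pass against the converged mean
    for i in range(n):
        R = _optimal_rotation(X[i], mean)
        X[i] = X[i] @ R.T
    mean = X.mean(axis=0)
    distances = np.linalg.norm(X - mean, axis=(1, 2))
    return ProcrustesResult(
        aligned=X, mean_shape=mean, centroid_sizes=sizes,
        distances=distances, with_scaling=with_scaling,
    )


def procrustes_distance(a, b, with_scaling: bool = True) -> float:
    """Closed-form two-configuration Procrustes distance.

    Both configurations are centered (and unit-scaled when ``with_scaling``),
    optimally rotated, and the Frobenius distance returned. Equals the
    inter-configuration distance of a two-shape GPA at convergence.
    """
    A, B = _stack([a, b])
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    if with_scaling:
        sa, sb = centroid_size(A), centroid_size(B)
        if sa < 1e-12 or sb < 1e-12:
            raise ProcrustesError("degenerate zero-size configuration")
        A, B = A / sa, B / sb
    R = _optimal_rotation(B, A)
    return float(np.linalg.norm(A - B @ R.T))
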