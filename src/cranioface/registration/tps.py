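"""3D thin-plate-spline warps with kernel U(r) = r."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..meshkit.landmarks import Configuration


class TPSError(ValueError):
    pass


def _as_points(x) -> np.ndarray:
    if isinstance(x, Configuration):
        return x.points
    return np.asarray(x, dtype=float).reshape(-1, 3)


def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.linalg.norm(diff, axis=2)


@dataclass
class TPSWarp:
    """f(x) = c + A x + sum_i w_i U(|x - s_i|) per output coordinate."""

    source: np.ndarray      # (k, 3) control points
    affine: np.ndarray      # (4, 3): row 0 translation, rows 1:4 linear map
    weights: np.ndarray     # (k, 3) non-affine kernel weights

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        K = _kernel(pts, self.source)
        return (
            self.affine[0]
            + pts @ self.affine[1:]
            + K @ self.weights
        )

    def bending_energy(self) -> float:
        """Non-negative bending norm, summed over output coordinates.

        The 3D biharmonic Green's function is -r/(8 pi), so the quadratic
        form is -w^T K w on the side-condition subspace; zero iff affine.
        """
        K = _kernel(self.source, self.source)
        return float(-np.einsum("ic,ij,jc->", self.weights, K, self.weights))


def tps_fit(source, target, regularization: float = 0.0) -> TPSWarp:
    """Fit a TPS interpolating (regularization 0) or smoothing warp.

    The solved weights satisfy the side conditions 1^T W = 0 and
    S^T W = 0, guaranteeing bounded non-affine behaviour at infinity.
    """
    src = _as_points(source)
    tgt = _as_points(target)
    if src.shape != tgt.shape:
        raise TPSError("source/target landmark counts differ")
    k = len(src)
    if k < 4:
        raise TPSError("need at least 4 control points")
    if regularization < 0:
        raise TPSError("regularization must be >= 0")
    K = _kernel(src, src) + regularization * np.eye(k)
    P = np.column_stack([np.ones(k), src])
    A = np.zeros((k + 4, k + 4))
    A[:k, :k] = K
    A[:k, k:] = P
    A[k:, :k] = P.T
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = tgt
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise TPSError("singular TPS system (coplanar or duplicated sources)") from exc
    cond = np.linalg.norm(A @ sol - rhs)
    if not np.isfinite(cond) or cond > 1e-4 * max(1.0, np.abs(tgt).max()) * k:
        raise TPSError("ill-conditioned TPS system (degenerate sources)")
    return TPSWarp(source=src.copy(), affine=sol[k:], weights=sol[:k])


def tps_apply(warp: TPSWarp, points) -> np.ndarray:
    return warp.apply(points)
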