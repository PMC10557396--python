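"""Closed-form least-squares similarity alignment (Kabsch-Umeyama)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class AlignmentError(ValueError):
    pass


@dataclass
class SimilarityTransform:
    """p -> S * R @ p + t with R in SO(3) and S > 0."""

    R: np.ndarray
    t: np.ndarray
    S: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.S * (np.asarray(points, dtype=float) @ self.R.T) + self.t

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.R.T
        Sinv = 1.0 / self.S
        return SimilarityTransform(Rinv, -Sinv * (Rinv @ self.t), Sinv)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)


def similarity_align(P: np.ndarray, Q: np.ndarray,
                     with_scaling: bool = True) -> SimilarityTransform:
    """Global minimizer of sum_i ||q_i - (S R p_i + t)||^2.

    Umeyama's SVD solution; a reflection guard flips the smallest singular
    axis when the optimal orthogonal map has negative determinant.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise AlignmentError("point sets must have equal shapes")
    m = len(P)
    if m < 3:
        raise AlignmentError("need at least 3 correspondences")
    mu_p = P.mean(axis=0)
    mu_q = Q.mean(axis=0)
    Pc = P - mu_p
    Qc = Q - mu_q
    var_p = (Pc ** 2).sum() / m
    if var_p < 1e-24:
        raise AlignmentError("source points are coincident")
    cov = Qc.T @ Pc / m
    U, D, Vt = np.linalg.svd(cov)
    sgn = np.ones(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        sgn[-1] = -1.0
    R = U @ np.diag(sgn) @ Vt
    if with_scaling:
        S = float((D * sgn).sum() / var_p)
        if S <= 0:
            raise AlignmentError("degenerate configuration: non-positive scale")
    else:
        S = 1.0
    t = mu_q - S * (R @ mu_p)
    return SimilarityTransform(R=R, t=t, S=S)


def alignment_objective(xf: SimilarityTransform, P: np.ndarray, Q: np.ndarray) -> float:
    diff = np.asarray(Q, dtype=float) - xf.apply(P)
    return float((diff ** 2).sum())
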