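"""Facial statistical shape model: construction, fitting, frame transfer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import SurfaceQuery
from ..meshkit.landmarks import Configuration
from ..meshkit.mesh import TriangleMesh
from ..morphometrics.gpa import gpa
from ..morphometrics.pca import pca_shapes
from ..registration.similarity import SimilarityTransform, similarity_align
from scipy.spatial import cKDTree


class SSMError(ValueError):
    pass


@dataclass
class FaceSSM:
    """Mean face + orthonormal PC modes over 3n stacked coordinates."""

    mean_face: np.ndarray        # (n_points, 3)
    basis: np.ndarray            # (d, 3n) orthonormal rows
    eigenvalues: np.ndarray      # (d,)
    scores: np.ndarray           # training scores (n_train, d)
    faces: np.ndarray | None = field(default=None)  # optional mesh topology

    @property
    def d(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_points(self) -> int:
        return len(self.mean_face)

    def synthesize(self, beta: np.ndarray) -> np.ndarray:
        """Mean face plus the scored combination of modes; beta=0 -> mean."""
        beta = np.asarray(beta, dtype=float)
        flat = self.mean_face.reshape(-1) + beta @ self.basis
        return flat.reshape(-1, 3)

    def mesh(self, beta: np.ndarray) -> TriangleMesh:
        if self.faces is None:
            raise SSMError("SSM carries no mesh topology")
        return TriangleMesh(self.synthesize(beta), self.faces.copy())


def build_ssm(face_configs, cumulative_threshold: float = 0.95,
              faces: np.ndarray | None = None) -> FaceSSM:
    """GPA (rigid, sizes kept in mm) then PCA over the cohort of faces."""
    configs = [
        c.points if isinstance(c, Configuration) else np.asarray(c, dtype=float)
        for c in face_configs
    ]
    if len(configs) < 3:
        raise SSMError("need at least 3 faces")
    aligned = gpa(configs, with_scaling=False)
    space = pca_shapes(aligned, cumulative_threshold)
    return FaceSSM(
        mean_face=space.mean_shape,
        basis=space.basis,
        eigenvalues=space.eigenvalues,
        scores=space.scores,
        faces=None if faces is None else np.asarray(faces, dtype=np.int64),
    )


def fit_ssm(ssm: FaceSSM, correspondences: list[tuple[np.ndarray, int]],
            lam: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Ridge fit of SSM coefficients to partial point correspondences.

    ``correspondences`` pairs an observed point ``tp_i`` (already in the SSM
    frame) with the index of its SSM mean-face point. Solves
    ``min ||U_s beta - (tp - mean)||^2 + lam^2 ||beta||^2`` in closed form
    over the corresponded coordinate rows, then synthesizes the full face —
    including geometry absent from the observations. ``lam`` defaults to
    ``1e-3 * sqrt(leading eigenvalue)``.
    """
    if not correspondences:
        raise SSMError("empty correspondence set")
    if lam is None:
        lam = 1e-3 * float(np.sqrt(ssm.eigenvalues[0])) if ssm.d else 0.0
    idx = np.array([int(i) for _, i in correspondences], dtype=np.int64)
    tp = np.array([p for p, _ in correspondences], dtype=float)
    if idx.min() < 0 or idx.max() >= ssm.n_points:
        raise SSMError("correspondence index out of range")
    rows = (3 * idx[:, None] + np.arange(3)[None, :]).reshape(-1)
    Us = ssm.basis[:, rows].T                      # (3m, d)
    resid = (tp - ssm.mean_face[idx]).reshape(-1)  # (3m,)
    A = Us.T @ Us + (lam ** 2) * np.eye(ssm.d)
    beta = np.linalg.solve(A, Us.T @ resid)
    return beta, ssm.synthesize(beta)


@dataclass
class FrameTransfer:
    transformed_points: np.ndarray          # coarse face carried into SSM frame
    transform: SimilarityTransform          # coarse frame -> SSM frame
    correspondences: list[tuple[np.ndarray, int]]
    n_dropped: int


def transform_to_ssm_frame(
    coarse_points: np.ndarray,
    coarse_envelope: TriangleMesh,
    deformed_average_face: TriangleMesh,
    ssm: FaceSSM,
    skull_points: np.ndarray,
    directions: np.ndarray,
    max_depth: float = 60.0,
) -> FrameTransfer:
    """Estimate the similarity carrying the coarse face into the SSM frame.

    Rays from the dry-skull points along the fixed measurement directions
    are intersected with both the coarse envelope and the deformed average
    face; each average-face hit is identified with its nearest SSM
    mean-face point index, pairing it with the coarse hit. Rays missing
    either surface are dropped (count reported).
    """
    skull_points = np.asarray(skull_points, dtype=float).reshape(-1, 3)
    directions = np.asarray(directions, dtype=float).reshape(-1, 3)
    q_coarse = SurfaceQuery(coarse_envelope)
    q_avg = SurfaceQuery(deformed_average_face)
    t_c, _ = q_coarse.raycast(skull_points, directions, max_dist=max_depth)
    t_a, _ = q_avg.raycast(skull_points, directions, max_dist=max_depth)
    ok = np.isfinite(t_c) & np.isfinite(t_a)
    n_dropped = int((~ok).sum())
    if ok.sum() < 3:
        raise SSMError("fewer than 3 valid ray pairs")
    hits_c = skull_points[ok] + t_c[ok, None] * directions[ok]
    hits_a = skull_points[ok] + t_a[ok, None] * directions[ok]
    # the average-face hit identifies the SSM point index; pair it with the
    # coarse hit to relate the two frames
    tree = cKDTree(deformed_average_face.vertices)
    _, vidx = tree.query(hits_a)
    xf = similarity_align(hits_c, ssm.mean_face[vidx])
    pairs = [(p, int(i)) for p, i in zip(xf.apply(hits_c), vidx)]
    return FrameTransfer(
        transformed_points=xf.apply(np.asarray(coarse_points, dtype=float)),
        transform=xf,
        correspondences=pairs,
        n_dropped=n_dropped,
    )
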