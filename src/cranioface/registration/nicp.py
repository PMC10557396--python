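"""Non-rigid ICP with per-vertex affine transforms and stiffness regularization.

Each template vertex carries a 3x4 affine transform; the objective combines
a data term (distance from transformed vertices to their closest compatible
target surface points), an edge-wise stiffness term penalizing differences
between neighbouring transforms, and optional soft landmark constraints.
Stiffness is relaxed over a schedule of stages; each stage iterates
correspondence search and a sparse linear solve to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix, kron
from scipy.sparse.linalg import spsolve

from ..geometry import SurfaceQuery
from ..meshkit.mesh import TriangleMesh, compute_vertex_normals
from .tps import TPSError, TPSWarp, tps_fit


DEFAULT_STIFFNESS = (50.0, 20.0, 10.0, 5.0, 2.0)


@dataclass
class NICPResult:
    deformed: TriangleMesh
    residuals: list[float]          # final mean correspondence distance per stage
    stiffness_schedule: tuple[float, ...]
    converged: bool = True
    transforms: np.ndarray | None = field(default=None, repr=False)  # (n, 4, 3)


def _homogeneous_data_matrix(vertices: np.ndarray) -> csr_matrix:
    """Sparse D with row i = [x_i y_i z_i 1] placed in columns 4i..4i+3."""
    n = len(vertices)
    data = np.column_stack([vertices, np.ones(n)]).ravel()
    rows = np.repeat(np.arange(n), 4)
    cols = np.arange(4 * n)
    return csr_matrix((data, (rows, cols)), shape=(n, 4 * n))


def _edge_stiffness_matrix(edges: np.ndarray, n: int, gamma: float = 1.0) -> csr_matrix:
    """kron(node-arc incidence, G) with G = diag(1, 1, 1, gamma)."""
    m = len(edges)
    data = np.concatenate([np.ones(m), -np.ones(m)])
    rows = np.concatenate([np.arange(m), np.arange(m)])
    cols = np.concatenate([edges[:, 0], edges[:, 1]])
    M = csr_matrix((data, (rows, cols)), shape=(m, n))
    G = csr_matrix(np.diag([1.0, 1.0, 1.0, gamma]))
    return kron(M, G).tocsr()


def nicp_register(
    template: TriangleMesh,
    target: TriangleMesh,
    landmark_pairs: list[tuple[int, np.ndarray]] | None = None,
    stiffness_schedule: tuple[float, ...] = DEFAULT_STIFFNESS,
    max_iter: int = 10,
    landmark_weight: float = 10.0,
    update_tol: float = 1e-3,
    prune_distance_factor: float = 4.0,
    prune_normal_deg: float = 60.0,
) -> NICPResult:
    """Register ``template`` onto ``target``'s surface.

    ``landmark_pairs`` are ``(template_vertex_index, target_point)`` soft
    constraints whose weight decays to 1 in the final stage. Deterministic:
    no randomness is involved.
    """
    if template.n_faces == 0 or target.n_faces == 0:
        raise ValueError("template and target must be non-empty meshes")
    n = template.n_vertices
    edges = template.edges()
    MG = _edge_stiffness_matrix(edges, n)
    MGtMG = (MG.T @ MG).tocsr()
    query = SurfaceQuery(target)
    target_with_normals = compute_vertex_normals(target)
    target_face_normals = target_with_normals.face_normals()

    # per-vertex transforms act on centroid-centered, unit-spread template
    # coordinates so the stiffness weight is scale-invariant (raw mm
    # coordinates would make the linear parts ~|v| times cheaper to vary
    # than the translations)
    c0 = template.centroid()
    s0 = float(np.linalg.norm(template.vertices - c0, axis=1).mean())
    if s0 <= 0:
        raise ValueError("degenerate template")
    Vn = (template.vertices - c0) / s0
    # initial transforms reproduce the template exactly
    X = np.tile(np.vstack([s0 * np.eye(3), c0]), (n, 1))  # (4n, 3)
    current = template.vertices.copy()
    cos_thresh = np.cos(np.radians(prune_normal_deg))
    D = _homogeneous_data_matrix(Vn)
    if landmark_pairs:
        lm_idx = np.array([i for i, _ in landmark_pairs], dtype=np.int64)
        lm_tgt = np.array([p for _, p in landmark_pairs], dtype=float)
        DL = D[lm_idx]
        DLtDL = (DL.T @ DL).tocsr()
        DLt_lm = DL.T @ lm_tgt

    residuals: list[float] = []
    converged = True
    n_stages = len(stiffness_schedule)
    for stage, alpha in enumerate(stiffness_schedule):
        beta = landmark_weight if stage < n_stages - 1 else 1.0
        stage_residual = np.inf
        stage_converged = False
        for _ in range(max_iter):
            tmpl_n = compute_vertex_normals(
                TriangleMesh(current, template.faces)
            ).normals
            cp, dist, fidx = query.closest_point(current)
            stage_residual = float(dist.mean())
            # prune incompatible correspondences
            w = np.ones(n)
            med = np.median(dist)
            if med > 0:
                w[dist > prune_distance_factor * med] = 0.0
            tn = target_face_normals[fidx]
            dots = np.einsum("ij,ij->i", tmpl_n, tn)
            w[np.abs(dots) < cos_thresh] = 0.0
            if w.sum() < 3:
                w[:] = 1.0
            W = csr_matrix((w, (np.arange(n), np.arange(n))), shape=(n, n))
            WD = W @ D
            AtA = (alpha ** 2) * MGtMG + (WD.T @ WD)
            AtB = WD.T @ (W @ cp)
            if landmark_pairs:
                AtA = AtA + (beta ** 2) * DLtDL
                AtB = AtB + (beta ** 2) * DLt_lm
            X_new = spsolve(AtA.tocsc(), AtB)
            if X_new.ndim == 1:
                X_new = X_new.reshape(-1, 3)
            update = float(np.linalg.norm(X_new - X) / max(1.0, np.linalg.norm(X)))
            X = X_new
            current = np.asarray(D @ X)
            if update < update_tol:
                stage_converged = True
                break
        _, dist, _ = query.closest_point(current)
        residuals.append(float(dist.mean()))
        converged = converged and stage_converged
    deformed = TriangleMesh(current, template.faces.copy())
    return NICPResult(
        deformed=deformed,
        residuals=residuals,
        stiffness_schedule=tuple(stiffness_schedule),
        converged=converged,
        transforms=X.reshape(n, 4, 3),
    )


@dataclass
class HybridResult:
    deformed: TriangleMesh
    tps_warp: TPSWarp
    nicp: NICPResult
    tps_residual: float
    final_residual: float


def hybrid_register(
    template: TriangleMesh,
    target: TriangleMesh,
    source_landmarks: np.ndarray,
    target_landmarks: np.ndarray,
    stiffness_schedule: tuple[float, ...] = DEFAULT_STIFFNESS,
    max_iter: int = 10,
    tps_regularization: float = 0.0,
    **nicp_kwargs,
) -> HybridResult:
    """TPS warp on landmarks, then NICP refinement from the warped template.

    Stage-2 landmark constraints reuse the landmark pairs, anchored at the
    template vertices nearest each source landmark.
    """
    source_landmarks = np.asarray(source_landmarks, dtype=float).reshape(-1, 3)
    target_landmarks = np.asarray(target_landmarks, dtype=float).reshape(-1, 3)
    if source_landmarks.shape != target_landmarks.shape:
        raise TPSError("mismatched landmark counts")
    warp = tps_fit(source_landmarks, target_landmarks, tps_regularization)
    warped = TriangleMesh(warp.apply(template.vertices), template.faces.copy())
    query = SurfaceQuery(target)
    _, d_tps, _ = query.closest_point(warped.vertices)
    tps_residual = float(d_tps.mean())
    # anchor landmark constraints at template vertices nearest the sources
    from scipy.spatial import cKDTree

    tree = cKDTree(template.vertices)
    _, lm_vidx = tree.query(source_landmarks)
    pairs = [(int(i), t) for i, t in zip(lm_vidx, target_landmarks)]
    nicp = nicp_register(
        warped, target, landmark_pairs=pairs,
        stiffness_schedule=stiffness_schedule, max_iter=max_iter, **nicp_kwargs,
    )
    _, d_fin, _ = query.closest_point(nicp.deformed.vertices)
    final_residual = float(d_fin.mean())
    if final_residual > tps_residual:
        # NICP must not make things worse; keep the TPS stage then
        nicp = NICPResult(
            deformed=warped, residuals=[tps_residual],
            stiffness_schedule=tuple(stiffness_schedule), converged=True,
        )
        final_residual = tps_residual
    return HybridResult(
        deformed=nicp.deformed,
        tps_warp=warp,
        nicp=nicp,
        tps_residual=tps_residual,
        final_residual=final_residual,
    )
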