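"""Laplacian-coordinate mesh deformation under soft anchor constraints."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix, identity, vstack as spvstack
from scipy.sparse.linalg import spsolve

from ..meshkit.mesh import TriangleMesh, connected_vertex_components


class LaplacianError(ValueError):
    pass


def uniform_laplacian(mesh: TriangleMesh) -> csr_matrix:
    """Graph Laplacian L with rows L_i = v_i - mean(neighbours)."""
    adj = mesh.vertex_adjacency().tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise LaplacianError("mesh has isolated vertices")
    inv_deg = 1.0 / deg
    W = csr_matrix(
        (adj.data * np.repeat(inv_deg, np.diff(adj.indptr)), adj.indices, adj.indptr),
        shape=adj.shape,
    )
    return identity(mesh.n_vertices, format="csr") - W


def cotangent_laplacian(mesh: TriangleMesh) -> csr_matrix:
    """Cotangent-weighted Laplacian (rows normalized by total weight)."""
    n = mesh.n_vertices
    v = mesh.vertices
    f = mesh.faces
    rows, cols, vals = [], [], []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # cotangent at vertex 'c' weights edge (a, b)
        e1 = v[f[:, a]] - v[f[:, c]]
        e2 = v[f[:, b]] - v[f[:, c]]
        cos = np.einsum("ij,ij->i", e1, e2)
        sin = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = cos / np.maximum(sin, 1e-12)
        rows += [f[:, a], f[:, b]]
        cols += [f[:, b], f[:, a]]
        vals += [cot, cot]
    W = csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    deg = np.asarray(W.sum(axis=1)).ravel()
    if np.any(np.abs(deg) < 1e-12):
        raise LaplacianError("degenerate cotangent weights")
    Wn = csr_matrix(
        (W.data * np.repeat(1.0 / deg, np.diff(W.indptr)), W.indices, W.indptr),
        shape=W.shape,
    )
    return identity(n, format="csr") - Wn


@dataclass
class RefinedFace:
    mesh: TriangleMesh
    anchor_indices: np.ndarray
    anchor_targets: np.ndarray
    anchor_residual_max: float
    anchor_weight: float


def laplacian_refine(fitted: TriangleMesh,
                     anchors: list[tuple[np.ndarray, int]] | dict[int, np.ndarray],
                     anchor_weight: float = 1.0,
                     operator: str = "uniform") -> RefinedFace:
    """Deform a mesh to meet anchors while preserving Laplacian coordinates.

    Minimizes ``sum_i ||L g_i - L v_i||^2 + w * sum_j ||g_j - l_j||^2`` in
    one sparse least-squares solve per coordinate. ``anchors`` maps vertex
    indices ``j`` to target positions ``l_j`` (dict, or list of ``(l_j, j)``
    pairs). Topology is preserved exactly.
    """
    if anchor_weight <= 0:
        raise LaplacianError("anchor_weight must be > 0")
    if isinstance(anchors, dict):
        items = sorted(anchors.items())
        idx = np.array([j for j, _ in items], dtype=np.int64)
        tgt = np.array([p for _, p in items], dtype=float)
    else:
        idx = np.array([j for _, j in anchors], dtype=np.int64)
        tgt = np.array([p for p, _ in anchors], dtype=float)
    if len(idx) == 0:
        raise LaplacianError("need at least one anchor")
    n = fitted.n_vertices
    if idx.min() < 0 or idx.max() >= n:
        raise LaplacianError("anchor index out of range")
    comp = connected_vertex_components(fitted)
    if not set(np.unique(comp)) <= set(np.unique(comp[idx])):
        raise LaplacianError("a connected component has no anchor: underdetermined")
    L = uniform_laplacian(fitted) if operator == "uniform" else cotangent_laplacian(fitted)
    delta = L @ fitted.vertices
    w = np.sqrt(anchor_weight)
    S = csr_matrix(
        (np.full(len(idx), w), (np.arange(len(idx)), idx)), shape=(len(idx), n)
    )
    A = spvstack([L, S]).tocsr()
    AtA = (A.T @ A).tocsc()
    rhs = A.T @ np.vstack([delta, w * tgt])
    g = spsolve(AtA, rhs)
    if g.ndim == 1:
        g = g.reshape(-1, 3)
    g = np.asarray(g)
    residual = float(np.linalg.norm(g[idx] - tgt, axis=1).max())
    return RefinedFace(
        mesh=TriangleMesh(g, fitted.faces.copy()),
        anchor_indices=idx,
        anchor_targets=tgt,
        anchor_residual_max=residual,
        anchor_weight=anchor_weight,
    )
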