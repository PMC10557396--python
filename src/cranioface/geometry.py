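"""Exact surface proximity and ray-intersection queries on triangle meshes.

Closest-point queries use a KD-tree over triangle centroids to shortlist
candidate triangles, then evaluate exact point-triangle distances
(Ericson's region decomposition). Ray casting is vectorized
Moller-Trumbore over candidate triangles.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .meshkit.mesh import TriangleMesh


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on triangle ``tri[i]`` to ``points[i]``, vectorized.

    Parameters
    ----------
    points : (n, 3)
    tri : (n, 3, 3)

    Returns
    -------
    closest : (n, 3)
    dist2 : (n,)
    """
    p = np.asarray(points, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    result = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex region A
    mask = (d1 <= 0) & (d2 <= 0)
    result[mask] = a[mask]
    done |= mask

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    mask = ~done & (d3 >= 0) & (d4 <= d3)
    result[mask] = b[mask]
    done |= mask

    vc = d1 * d4 - d3 * d2
    mask = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    result[mask] = a[mask] + v[mask, None] * ab[mask]
    done |= mask

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    mask = ~done & (d6 >= 0) & (d5 <= d6)
    result[mask] = c[mask]
    done |= mask

    vb = d5 * d2 - d1 * d6
    mask = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    result[mask] = a[mask] + w[mask, None] * ac[mask]
    done |= mask

    va = d3 * d6 - d5 * d4
    mask = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = (d4 - d3) + (d5 - d6)
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    result[mask] = b[mask] + w[mask, None] * (c[mask] - b[mask])
    done |= mask

    # interior
    mask = ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v = vb / denom
        w = vc / denom
    result[mask] = a[mask] + v[mask, None] * ab[mask] + w[mask, None] * ac[mask]

    diff = p - result
    return result, np.einsum("ij,ij->i", diff, diff)


class SurfaceQuery:
    """Accelerated proximity/ray queries against a fixed triangle mesh."""

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise ValueError("mesh has no faces")
        self.mesh = mesh
        self._tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
        self._centroids = self._tri.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        # circumscribing radius per triangle, used to make shortlists safe
        self._tri_radius = np.linalg.norm(
            self._tri - self._centroids[:, None, :], axis=2
        ).max(axis=1)
        self._max_tri_radius = float(self._tri_radius.max())

    def closest_point(self, points: np.ndarray, k: int = 12) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest surface points, distances and face indices.

        A KD-tree shortlist of ``k`` centroid-nearest triangles is widened by
        a conservative radius search so the exact minimum cannot be missed.
        Ties are broken toward the lowest face index.
        """
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        n = len(points)
        k = min(k, self.mesh.n_faces)
        d_cent, idx = self._tree.query(points, k=k)
        if k == 1:
            d_cent = d_cent[:, None]
            idx = idx[:, None]
        best_pt = np.empty((n, 3))
        best_d2 = np.full(n, np.inf)
        best_face = np.zeros(n, dtype=np.int64)
        self._scan(points, idx, best_pt, best_d2, best_face)
        # widen: any triangle whose centroid is within best_d + tri_radius
        # could still be closer
        bound = np.sqrt(best_d2) + self._max_tri_radius
        need = bound > d_cent[:, -1] - 1e-12
        if np.any(need) and k < self.mesh.n_faces:
            sub = np.flatnonzero(need)
            lists = self._tree.query_ball_point(points[sub], bound[sub])
            for j, cand in zip(sub, lists):
                cand = np.asarray(cand, dtype=np.int64)
                if len(cand) == 0:
                    continue
                tri = self._tri[cand]
                cp, d2 = closest_point_on_triangles(
                    np.repeat(points[j][None], len(cand), axis=0), tri
                )
                order = np.lexsort((cand, d2))
                b = order[0]
                if d2[b] < best_d2[j] - 1e-15 or (
                    abs(d2[b] - best_d2[j]) <= 1e-15 and cand[b] < best_face[j]
                ):
                    best_d2[j] = d2[b]
                    best_pt[j] = cp[b]
                    best_face[j] = cand[b]
        return best_pt, np.sqrt(best_d2), best_face

    def _scan(self, points, idx, best_pt, best_d2, best_face) -> None:
        n, k = idx.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_idx = idx.reshape(-1)
        cp, d2 = closest_point_on_triangles(flat_pts, self._tri[flat_idx])
        cp = cp.reshape(n, k, 3)
        d2 = d2.reshape(n, k)
        # lowest face index among (near-)minimal distances
        jbest = np.argmin(d2 + 1e-15 * flat_idx.reshape(n, k), axis=1)
        rows = np.arange(n)
        best_d2[:] = d2[rows, jbest]
        best_pt[:] = cp[rows, jbest]
        best_face[:] = idx[rows, jbest]

    def raycast(self, origins: np.ndarray, directions: np.ndarray,
                max_dist: float = np.inf) -> tuple[np.ndarray, np.ndarray]:
        """First-hit distances along rays; NaN where no hit within ``max_dist``.

        Returns ``(t, face_index)``; ``face_index`` is -1 for misses. Only
        forward intersections (t >= 0) count.
        """
        origins = np.asarray(origins, dtype=float).reshape(-1, 3)
        directions = np.asarray(directions, dtype=float).reshape(-1, 3)
        n = len(origins)
        t_out = np.full(n, np.nan)
        f_out = np.full(n, -1, dtype=np.int64)
        a = self._tri[:, 0]
        e1 = self._tri[:, 1] - a
        e2 = self._tri[:, 2] - a
        # chunk rays to bound memory: n_rays x n_tris temporary arrays
        m = self.mesh.n_faces
        chunk = max(1, int(4_000_000 // max(m, 1)))
        for s in range(0, n, chunk):
            o = origins[s : s + chunk]
            d = directions[s : s + chunk]
            t, fi = _moller_trumbore(o, d, a, e1, e2, max_dist)
            t_out[s : s + chunk] = t
            f_out[s : s + chunk] = fi
        return t_out, f_out


def _moller_trumbore(o, d, a, e1, e2, max_dist):
    eps = 1e-12
    # pvec: (r, m, 3)
    pvec = np.cross(d[:, None, :], e2[None, :, :])
    det = np.einsum("mj,rmj->rm", e1, pvec)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_det = np.where(np.abs(det) > eps, 1.0 / det, np.nan)
    tvec = o[:, None, :] - a[None, :, :]
    u = np.einsum("rmj,rmj->rm", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rj,rmj->rm", d, qvec) * inv_det
    t = np.einsum("mj,rmj->rm", e2, qvec) * inv_det
    tol = 1e-9
    valid = (
        np.isfinite(t)
        & (u >= -tol)
        & (v >= -tol)
        & (u + v <= 1 + tol)
        & (t >= -1e-9)
        & (t <= max_dist)
    )
    t = np.where(valid, t, np.inf)
    fi = np.argmin(t, axis=1)
    tmin = t[np.arange(len(o)), fi]
    hit = np.isfinite(tmin)
    return np.where(hit, tmin, np.nan), np.where(hit, fi, -1)
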