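"""Point-cloud to triangle-mesh reconstruction.

Every output vertex is an input point and faces only connect points within
the largest allowed ball radius. Two complementary strategies cover the
surfaces this toolkit produces: coplanar clouds are triangulated by planar
Delaunay; closed star-shaped clouds (heads, envelopes) by a spherical
Delaunay triangulation (convex hull of the points' unit directions about
their centroid). Triangles with any edge longer than the largest radius are
discarded, which mimics the ball-size limit of pivoting-style
reconstruction.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from .mesh import MeshError, TriangleMesh


class ReconstructionError(ValueError):
    """Raised when a point cloud cannot be meshed."""


def median_spacing(points: np.ndarray) -> float:
    """Median nearest-neighbour distance of the cloud."""
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(np.median(d[:, 1]))


def default_radii(points: np.ndarray) -> list[float]:
    """Ball radii {1, 2, 4} x median nearest-neighbour spacing."""
    h = median_spacing(points)
    return [h, 2.0 * h, 4.0 * h]


def reconstruct_surface(points: np.ndarray, radii: list[float] | None = None) -> TriangleMesh:
    """Mesh a point cloud; see module docstring for the strategy.

    Parameters
    ----------
    points : (n, 3) array, n >= 4, not all collinear
    radii : increasing ball radii (mm); faces with edges longer than
        ``max(radii)`` are rejected. Defaults to :func:`default_radii`.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 4:
        raise ReconstructionError("need at least 4 points")
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = svals[0]
    if scale <= 0 or svals[1] < 1e-9 * scale:
        raise ReconstructionError("degenerate (collinear) point cloud")
    if radii is None:
        radii = default_radii(points)
    r_max = float(max(radii))
    if svals[2] < 1e-7 * scale:
        faces = _planar_triangulation(points)
    else:
        faces = _star_triangulation(points)
    faces = _filter_long_edges(points, faces, r_max)
    if len(faces) == 0:
        raise ReconstructionError("no faces within the allowed ball radius")
    try:
        return TriangleMesh(points, faces)
    except MeshError as exc:  # pragma: no cover - defensive
        raise ReconstructionError(str(exc)) from exc


def _planar_triangulation(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    uv = centered @ vt[:2].T
    tri = Delaunay(uv)
    return tri.simplices.astype(np.int64)


def _star_triangulation(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    norms = np.linalg.norm(centered, axis=1)
    if np.any(norms < 1e-12):
        raise ReconstructionError("point coincides with the cloud centroid")
    dirs = centered / norms[:, None]
    hull = ConvexHull(dirs)
    faces = hull.simplices.astype(np.int64)
    # orient faces outward w.r.t. the centroid
    tri = centered[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", n, tri.mean(axis=1)) < 0
    faces[flip] = faces[flip][:, ::-1]
    return faces


def _filter_long_edges(points: np.ndarray, faces: np.ndarray, r_max: float) -> np.ndarray:
    tri = points[faces]
    e = np.stack(
        [
            np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1),
            np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1),
            np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1),
        ]
    )
    return faces[e.max(axis=0) <= r_max]
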