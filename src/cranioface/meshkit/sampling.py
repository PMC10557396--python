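"""Blue-noise (Poisson-disk) semilandmark sampling on triangle meshes."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from ..geometry import SurfaceQuery
from .landmarks import Configuration
from .mesh import TriangleMesh


def sample_surface_uniform(mesh: TriangleMesh, n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-weighted uniform random points on the surface."""
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    fidx = rng.choice(mesh.n_faces, size=n, p=areas / total)
    r1 = rng.random(n)
    r2 = rng.random(n)
    sqrt_r1 = np.sqrt(r1)
    u = 1.0 - sqrt_r1
    v = sqrt_r1 * (1.0 - r2)
    w = sqrt_r1 * r2
    tri = mesh.vertices[mesh.faces[fidx]]
    return u[:, None] * tri[:, 0] + v[:, None] * tri[:, 1] + w[:, None] * tri[:, 2]


def _dart_throw(candidates: np.ndarray, radius: float,
                tree: cKDTree | None = None) -> np.ndarray:
    """Greedy maximal subset with pairwise spacing >= radius (in input order)."""
    n = len(candidates)
    if tree is None:
        tree = cKDTree(candidates)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    # symmetric CSR adjacency over conflicting candidate pairs
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    indptr = np.searchsorted(src, np.arange(n + 1))
    blocked = np.zeros(n, dtype=bool)
    accepted: list[int] = []
    for i in range(n):
        if blocked[i]:
            continue
        accepted.append(i)
        blocked[dst[indptr[i]:indptr[i + 1]]] = True
    return np.asarray(accepted, dtype=np.int64)


def poisson_disk_sample(mesh: TriangleMesh, n_target: int, seed: int = 0,
                        tolerance: float = 0.02, max_bisect: int = 30) -> Configuration:
    """Poisson-disk sample approximately ``n_target`` surface points.

    The disk radius is found by bisection until the accepted count is within
    ``tolerance`` (default +-2%) of ``n_target``. Deterministic given
    ``seed``. The returned points keep the blue-noise minimum-spacing
    property: pairwise distances >= the final radius, which stays above half
    of ``sqrt(area / n_target)``.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    area = mesh.area()
    if area <= 0:
        raise ValueError("mesh has zero surface area")
    rng = np.random.default_rng(seed)
    n_cand = min(max(int(8 * n_target), 64), 400_000)
    candidates = sample_surface_uniform(mesh, n_cand, rng)
    cand_tree = cKDTree(candidates)
    # random-sequential-adsorption saturation gives ~0.68 * area / r^2 points
    r = float(np.sqrt(0.68 * area / n_target))
    lo, hi = 0.0, None
    best = None
    for _ in range(max_bisect):
        idx = _dart_throw(candidates, r, tree=cand_tree)
        count = len(idx)
        if best is None or abs(count - n_target) < abs(len(best[0]) - n_target):
            best = (idx, r)
        if abs(count - n_target) <= tolerance * n_target:
            best = (idx, r)
            break
        if count > n_target:  # too dense -> widen radius
            lo = r
            r = 2 * r if hi is None else 0.5 * (r + hi)
        else:
            hi = r
            r = 0.5 * (r + lo)
    idx, r = best
    count = len(idx)
    if abs(count - n_target) > tolerance * n_target:
        warnings.warn(
            f"poisson_disk_sample: achieved {count} points for target "
            f"{n_target} (best effort; density limit reached)",
            stacklevel=2,
        )
    points = candidates[idx]
    return Configuration(points, n_landmarks=0, n_semilandmarks=len(points))


def project_points_to_surface(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Nearest-surface-point projection (order preserved)."""
    return SurfaceQuery(mesh).closest_point(points)[0]
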