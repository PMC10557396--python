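"""Facial soft-tissue depth measurement, statistics and envelope generation.

Depths are measured by casting a ray from each skull point along a fixed
per-point direction (taken from the cohort-average skull and reused
unchanged for every specimen) and recording the distance to the first
facial-surface intersection. The inverse operation places each face point
at ``h_i = s_i + n_i * d_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..geometry import SurfaceQuery
from ..meshkit.landmarks import Configuration
from ..meshkit.mesh import TriangleMesh
from ..meshkit.reconstruct import reconstruct_surface

DEFAULT_MAX_DEPTH_MM = 60.0


class FSTDError(ValueError):
    pass


@dataclass
class FSTDField:
    """Per-point soft-tissue depths for one specimen."""

    skull_points: np.ndarray    # (k, 3)
    directions: np.ndarray      # (k, 3) unit vectors, cohort-constant
    depths: np.ndarray          # (k,) mm, NaN where the ray missed

    def __post_init__(self) -> None:
        self.skull_points = np.asarray(self.skull_points, dtype=float).reshape(-1, 3)
        self.directions = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        self.depths = np.asarray(self.depths, dtype=float).reshape(-1)
        k = len(self.skull_points)
        if len(self.directions) != k or len(self.depths) != k:
            raise FSTDError("skull points, directions and depths must align")
        if np.nanmin(self.depths, initial=0.0) < 0:
            raise FSTDError("negative depth")

    @property
    def measured(self) -> np.ndarray:
        return np.isfinite(self.depths)

    def face_points(self) -> np.ndarray:
        """Implied facial points h_i = s_i + n_i * d_i (NaN where missing)."""
        return self.skull_points + self.directions * self.depths[:, None]


@dataclass
class FSTDStatistics:
    point_mean: np.ndarray      # (k,) mm, NaN where never measured
    point_sd: np.ndarray        # (k,) sample SD (ddof=1), NaN where n<2
    point_count: np.ndarray     # (k,) specimens contributing
    cohort_mean: float
    cohort_sd: float


def measure_fstd(skull_config, directions: np.ndarray, face: TriangleMesh,
                 max_depth: float = DEFAULT_MAX_DEPTH_MM) -> FSTDField:
    """Cast one ray per skull point; missing intersections yield NaN depths."""
    if face.n_faces == 0:
        raise FSTDError("empty face mesh")
    pts = skull_config.points if isinstance(skull_config, Configuration) else \
        np.asarray(skull_config, dtype=float).reshape(-1, 3)
    directions = np.asarray(directions, dtype=float).reshape(-1, 3)
    if len(directions) != len(pts):
        raise FSTDError("one direction per skull point required")
    t, _ = SurfaceQuery(face).raycast(pts, directions, max_dist=max_depth)
    return FSTDField(skull_points=pts, directions=directions, depths=t)


def fstd_statistics(fields: list[FSTDField]) -> FSTDStatistics:
    """Per-point and cohort-wide depth statistics; NaN depths are excluded."""
    if not fields:
        raise FSTDError("need at least one field")
    k = len(fields[0].depths)
    for f in fields:
        if len(f.depths) != k:
            raise FSTDError("fields have differing point counts")
    D = np.stack([f.depths for f in fields])  # (n, k)
    count = np.isfinite(D).sum(axis=0)
    sums = np.nansum(np.where(np.isfinite(D), D, 0.0), axis=0)
    mean = np.where(count > 0, sums / np.maximum(count, 1), np.nan)
    sd = np.full(k, np.nan)
    multi = count >= 2
    if multi.any():
        sd[multi] = np.nanstd(D[:, multi], axis=0, ddof=1)
    all_depths = D[np.isfinite(D)]
    if all_depths.size == 0:
        raise FSTDError("no measured depths in the cohort")
    return FSTDStatistics(
        point_mean=mean,
        point_sd=sd,
        point_count=count,
        cohort_mean=float(all_depths.mean()),
        cohort_sd=float(all_depths.std(ddof=1)) if all_depths.size > 1 else 0.0,
    )


def impute_missing_depths(skull_points: np.ndarray, depths: np.ndarray,
                          k_neighbors: int = 8) -> np.ndarray:
    """Fill NaN depths by inverse-distance-weighted nearest measured points."""
    depths = np.asarray(depths, dtype=float).copy()
    missing = ~np.isfinite(depths)
    if not missing.any():
        return depths
    measured = np.flatnonzero(~missing)
    if len(measured) == 0:
        raise FSTDError("all depths missing; cannot impute")
    tree = cKDTree(skull_points[measured])
    kq = min(k_neighbors, len(measured))
    dist, idx = tree.query(skull_points[missing], k=kq)
    dist = np.atleast_2d(dist.reshape(len(idx), -1))
    idx = np.atleast_2d(idx.reshape(len(idx), -1))
    w = 1.0 / np.maximum(dist, 1e-9)
    vals = depths[measured][idx]
    depths[missing] = (w * vals).sum(axis=1) / w.sum(axis=1)
    return depths


def build_envelope(dry_skull_config, directions: np.ndarray,
                   mean_depths: np.ndarray,
                   radii: list[float] | None = None,
                   mesh_output: bool = True) -> tuple[np.ndarray, TriangleMesh | None]:
    """Offset skull points along fixed directions by (imputed) mean depths.

    Returns the envelope points and, when ``mesh_output``, their
    reconstructed triangle mesh.
    """
    pts = dry_skull_config.points if isinstance(dry_skull_config, Configuration) \
        else np.asarray(dry_skull_config, dtype=float).reshape(-1, 3)
    directions = np.asarray(directions, dtype=float).reshape(-1, 3)
    mean_depths = np.asarray(mean_depths, dtype=float).reshape(-1)
    if not (len(pts) == len(directions) == len(mean_depths)):
        raise FSTDError("points, directions and depths must align")
    depths = impute_missing_depths(pts, mean_depths)
    envelope = pts + directions * depths[:, None]
    mesh = reconstruct_surface(envelope, radii) if mesh_output else None
    return envelope, mesh
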