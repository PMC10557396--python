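"""Resemblance metrics and top-k recognition."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..geometry import SurfaceQuery
from ..meshkit.landmarks import Configuration
from ..meshkit.mesh import TriangleMesh
from ..morphometrics.gpa import procrustes_distance
from ..registration.similarity import similarity_align


class EvaluationError(ValueError):
    pass


@dataclass
class EvaluationConfig:
    """Evaluation landmark scheme: point picks + Procrustes scaling flag."""

    landmark_indices: np.ndarray       # 16 named-landmark analogues
    semilandmark_indices: np.ndarray   # 59 sampled points
    with_scaling: bool = False
    recognition_k: tuple[int, ...] = (1, 3)

    def __post_init__(self) -> None:
        self.landmark_indices = np.asarray(self.landmark_indices, dtype=np.int64)
        self.semilandmark_indices = np.asarray(self.semilandmark_indices, dtype=np.int64)
        if len(self.landmark_indices) != 16 or len(self.semilandmark_indices) != 59:
            raise EvaluationError("scheme must have 16 landmarks + 59 semilandmarks")
        if min(self.recognition_k, default=1) < 1:
            raise EvaluationError("recognition k must be >= 1")

    @property
    def indices(self) -> np.ndarray:
        return np.concatenate([self.landmark_indices, self.semilandmark_indices])

    def extract(self, mesh: TriangleMesh) -> Configuration:
        return Configuration(mesh.vertices[self.indices], n_landmarks=16)


def default_eval_config(n_vertices: int, landmark_indices: np.ndarray,
                        with_scaling: bool = False) -> EvaluationConfig:
    """75-point scheme: 16 given landmark picks + 59 evenly spread vertices."""
    lm = np.asarray(landmark_indices, dtype=np.int64)[:16]
    if len(lm) < 16:
        raise EvaluationError("need at least 16 landmark indices")
    pool = np.setdiff1d(np.arange(n_vertices), lm)
    semi = pool[np.linspace(0, len(pool) - 1, 59).round().astype(np.int64)]
    return EvaluationConfig(lm, np.unique(semi)[:59] if len(np.unique(semi)) >= 59
                            else semi, with_scaling=with_scaling)


@dataclass
class ResemblanceResult:
    procrustes: float
    mean_dense_mm: float
    deviation_field: np.ndarray   # per approx-vertex distance to actual surface


def resemblance(approx: TriangleMesh, actual: TriangleMesh,
                eval_approx: Configuration, eval_actual: Configuration,
                with_scaling: bool = False) -> ResemblanceResult:
    """Procrustes distance on the evaluation points + dense surface distance.

    The superimposing transform is estimated on the evaluation scheme and
    applied to the full approx mesh; the dense distance is directional
    (approx -> actual nearest surface point).
    """
    if eval_approx.k != eval_actual.k:
        raise EvaluationError("evaluation point counts differ")
    pd = procrustes_distance(eval_approx.points, eval_actual.points,
                             with_scaling=with_scaling)
    xf = similarity_align(eval_approx.points, eval_actual.points,
                          with_scaling=with_scaling)
    moved = xf.apply(approx.vertices)
    _, dist, _ = SurfaceQuery(actual).closest_point(moved)
    return ResemblanceResult(
        procrustes=float(pd),
        mean_dense_mm=float(dist.mean()),
        deviation_field=dist,
    )


def recognition_rate(approx_configs: list[Configuration],
                     pool_configs: list[Configuration],
                     k: int = 1,
                     true_indices: list[int] | None = None,
                     with_scaling: bool = False,
                     distance=None) -> tuple[float, np.ndarray]:
    """Top-k recognition percentage and the per-specimen rank of the truth.

    Pool faces are ranked by Procrustes distance ascending, ties broken by
    pool index (stable); a hit requires the true counterpart's rank <= k.
    """
    n = len(approx_configs)
    if true_indices is None:
        true_indices = list(range(n))
    if len(pool_configs) < k:
        raise EvaluationError("pool smaller than k")
    if distance is None:
        def distance(a, b):
            return procrustes_distance(a.points, b.points, with_scaling=with_scaling)
    # warn about duplicate pool entries
    seen = {}
    for j, cfg in enumerate(pool_configs):
        key = cfg.points.tobytes()
        if key in seen:
            warnings.warn(f"duplicate pool entries {seen[key]} and {j}; "
                          "first occurrence used", stacklevel=2)
        else:
            seen[key] = j
    ranks = np.empty(n, dtype=np.int64)
    for i in range(n):
        d = np.array([distance(approx_configs[i], p) for p in pool_configs])
        order = np.lexsort((np.arange(len(d)), d))  # stable: index breaks ties
        ranks[i] = int(np.flatnonzero(order == true_indices[i])[0]) + 1
    hits = int(np.sum(ranks <= k))
    return 100.0 * hits / n, ranks
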