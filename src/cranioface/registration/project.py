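"""Nearest-surface projection of semilandmark configurations."""

from __future__ import annotations

import numpy as np

from ..geometry import SurfaceQuery
from ..meshkit.landmarks import Configuration
from ..meshkit.mesh import TriangleMesh


def project_semilandmarks(points, target: TriangleMesh) -> Configuration:
    """Project each point to its nearest point on the target surface.

    Ordering is preserved; ties between equidistant faces break toward the
    lowest face index.
    """
    if target.n_faces == 0:
        raise ValueError("target mesh has no faces")
    if isinstance(points, Configuration):
        pts = points.points
        nl, ns = points.n_landmarks, points.n_semilandmarks
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        nl, ns = 0, len(pts)
    projected, _, _ = SurfaceQuery(target).closest_point(pts)
    return Configuration(projected, n_landmarks=nl, n_semilandmarks=ns)
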