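"""Similarity placement of predicted components onto the facial envelope.

Boundary loops of the component and of its target rim on the envelope are
resampled to a fixed number of points by normalized arc length; the cyclic
offset and traversal direction are chosen by exhaustive search to minimize
the post-alignment RMS, and the closed-form similarity transform is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..meshkit.boundary import boundary_loops_of_mesh, extract_boundary_loops
from ..meshkit.landmarks import ComponentLabels
from ..meshkit.mesh import TriangleMesh
from ..registration.similarity import SimilarityTransform, similarity_align


class PlacementError(ValueError):
    pass


def resample_loop(points: np.ndarray, m: int = 100) -> np.ndarray:
    """Resample a closed polyline to m points at equal normalized arc length."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise PlacementError("loop needs at least 3 vertices")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise PlacementError("degenerate zero-length loop")
    s = np.linspace(0.0, total, m, endpoint=False)
    idx = np.searchsorted(cum, s, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (s - cum[idx]) / np.maximum(seg[idx], 1e-300)
    return closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])


def match_loops(source_loop: np.ndarray, target_loop: np.ndarray,
                m: int = 100) -> tuple[np.ndarray, np.ndarray, SimilarityTransform]:
    """Best similarity alignment of one closed loop onto another.

    Both loops are resampled to ``m`` points; all ``m`` cyclic offsets in
    both traversal directions are tried (2m candidate correspondences) and
    the minimizer of the aligned RMS wins.
    """
    if m < 3:
        raise PlacementError("need at least 3 matched loop points")
    src = resample_loop(source_loop, m)
    tgt = resample_loop(target_loop, m)
    best = None
    for direction in (1, -1):
        s = src if direction == 1 else src[::-1]
        for offset in range(m):
            cand = np.roll(s, -offset, axis=0)
            xf = similarity_align(cand, tgt)
            rms = float(np.sqrt(np.mean(np.sum((xf.apply(cand) - tgt) ** 2, axis=1))))
            if best is None or rms < best[0]:
                best = (rms, cand, xf)
    _, matched_src, xf = best
    return matched_src, tgt, xf


@dataclass
class PlacementResult:
    placed_points: np.ndarray
    transform: SimilarityTransform
    boundary_rms_before: float
    boundary_rms_after: float


def place_component(component_mesh: TriangleMesh, envelope_mesh: TriangleMesh,
                    envelope_labels: ComponentLabels, component_id: str,
                    m: int = 100) -> PlacementResult:
    """Fit a component onto its envelope rim by boundary-curve alignment."""
    comp_loops = boundary_loops_of_mesh(component_mesh)
    if len(comp_loops) != 1:
        raise PlacementError(
            f"component must expose exactly 1 boundary loop, found {len(comp_loops)}"
        )
    env_loops = extract_boundary_loops(envelope_mesh, envelope_labels, component_id)
    if len(env_loops) != 1:
        raise PlacementError(
            f"envelope component {component_id!r} must expose exactly 1 loop, "
            f"found {len(env_loops)}"
        )
    src_pts = component_mesh.vertices[comp_loops[0]]
    tgt_pts = envelope_mesh.vertices[env_loops[0]]
    matched_src, tgt, xf = match_loops(src_pts, tgt_pts, m)
    before = float(np.sqrt(np.mean(np.sum((matched_src - tgt) ** 2, axis=1))))
    after = float(np.sqrt(np.mean(np.sum((xf.apply(matched_src) - tgt) ** 2, axis=1))))
    if after > before:  # similarity fit can never beat identity on its own objective
        xf = SimilarityTransform.identity()
        after = before
    return PlacementResult(
        placed_points=xf.apply(component_mesh.vertices),
        transform=xf,
        boundary_rms_before=before,
        boundary_rms_after=after,
    )
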