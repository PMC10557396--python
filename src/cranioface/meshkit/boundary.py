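"""Boundary-loop extraction for labelled mesh components."""

from __future__ import annotations

import numpy as np

from .landmarks import ComponentLabels
from .mesh import TriangleMesh


class BoundaryError(ValueError):
    pass


def boundary_loops_of_mesh(mesh: TriangleMesh) -> list[np.ndarray]:
    """Closed vertex loops along edges incident to exactly one face.

    Loops follow the winding induced by the face orientation (each boundary
    edge is traversed in its single incident face's direction), so windings
    are consistent across loops of a coherently oriented mesh.
    """
    f = mesh.faces
    if len(f) == 0:
        return []
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = directed[counts[inverse] == 1]
    if len(boundary) == 0:
        return []
    nxt = {}
    for a, b in boundary:
        nxt[int(a)] = int(b)
    loops: list[np.ndarray] = []
    remaining = set(nxt)
    while remaining:
        start = min(remaining)
        loop = [start]
        remaining.discard(start)
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            remaining.discard(cur)
            if cur not in nxt:
                raise BoundaryError("open boundary chain: mesh is not edge-manifold")
            cur = nxt[cur]
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def extract_boundary_loops(mesh: TriangleMesh, labels: ComponentLabels,
                           component: str) -> list[np.ndarray]:
    """Boundary loops of one labelled component, as original vertex indices."""
    if component not in set(labels.labels.tolist()):
        raise BoundaryError(f"component {component!r} not present in labels")
    sub, used = mesh.submesh(labels.mask(component))
    loops = boundary_loops_of_mesh(sub)
    return [used[loop] for loop in loops]
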