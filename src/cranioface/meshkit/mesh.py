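"""Triangle mesh container and basic differential geometry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


class MeshError(ValueError):
    """Raised for malformed or degenerate mesh data."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Vertex-index triples. Every index must be < ``n`` and no face may
        repeat a vertex.
    normals : (n, 3) float array, optional
        Per-vertex unit normals.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshError(
                    f"face index out of range: max index {self.faces.max()} "
                    f"on {len(self.vertices)} vertices"
                )
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise MeshError(
                    f"face {int(np.flatnonzero(degenerate)[0])} repeats a vertex"
                )
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if len(self.normals) != len(self.vertices):
                raise MeshError("normal count must equal vertex count")

    # -- basic quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.normals is None else self.normals.copy(),
        )

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        """Per-face normals; raw cross products carry twice the face area."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        if normalized:
            norm = np.linalg.norm(cross, axis=1, keepdims=True)
            norm[norm == 0.0] = 1.0
            cross = cross / norm
        return cross

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalized=False), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def edges(self, unique: bool = True) -> np.ndarray:
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        if unique:
            e = np.unique(np.sort(e, axis=1), axis=0)
        return e

    def vertex_adjacency(self) -> coo_matrix:
        e = self.edges()
        n = self.n_vertices
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return coo_matrix((data, (rows, cols)), shape=(n, n))

    def submesh(self, vertex_mask: np.ndarray) -> tuple["TriangleMesh", np.ndarray]:
        """Restrict to faces whose three vertices are all inside the mask.

        Returns the submesh and the original vertex indices of its vertices.
        """
        vertex_mask = np.asarray(vertex_mask, dtype=bool)
        keep_face = vertex_mask[self.faces].all(axis=1)
        used = np.unique(self.faces[keep_face])
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[used] = np.arange(len(used))
        sub = TriangleMesh(
            self.vertices[used],
            remap[self.faces[keep_face]],
            None if self.normals is None else self.normals[used],
        )
        return sub, used


def compute_vertex_normals(mesh: TriangleMesh, outward: bool = True) -> TriangleMesh:
    """Attach area-weighted, consistently oriented per-vertex unit normals.

    Face orientation is first unified by propagating a coherent winding
    across the face adjacency graph; outwardness is then fixed by majority
    vote of ``normal . (v - centroid) > 0``.
    """
    if mesh.n_faces < 1:
        raise MeshError("mesh has no faces")
    faces = _coherent_faces(mesh)
    oriented = TriangleMesh(mesh.vertices, faces)
    fn = oriented.face_normals(normalized=False)  # area-weighted
    normals = np.zeros_like(mesh.vertices)
    for c in range(3):
        np.add.at(normals, faces[:, c], fn)
    lengths = np.linalg.norm(normals, axis=1)
    zero = lengths < 1e-300
    if zero.any():
        # isolated vertices or degenerate stars: flag with NaN
        normals[zero] = np.nan
        lengths[zero] = 1.0
    normals = normals / lengths[:, None]
    if outward:
        rel = mesh.vertices - mesh.centroid()
        votes = np.einsum("ij,ij->i", normals[~zero], rel[~zero])
        if np.sum(votes > 0) < np.sum(votes < 0):
            normals = -normals
    return TriangleMesh(mesh.vertices, faces, normals)


def _coherent_faces(mesh: TriangleMesh) -> np.ndarray:
    """Flip faces so adjacent faces traverse shared edges in opposite order."""
    faces = mesh.faces.copy()
    m = len(faces)
    # map undirected edge -> incident faces
    edge_key = {}
    for fi in range(m):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(faces[fi, a], faces[fi, b]), max(faces[fi, a], faces[fi, b]))
            edge_key.setdefault(key, []).append(fi)
    # adjacency over faces
    visited = np.zeros(m, dtype=bool)
    for seed in range(m):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            fi = stack.pop()
            f = faces[fi]
            directed = {(f[0], f[1]), (f[1], f[2]), (f[2], f[0])}
            for a, b in ((0, 1), (1, 2), (2, 0)):
                key = (min(f[a], f[b]), max(f[a], f[b]))
                for fj in edge_key[key]:
                    if visited[fj] or fj == fi:
                        continue
                    g = faces[fj]
                    other = {(g[0], g[1]), (g[1], g[2]), (g[2], g[0])}
                    # consistent orientation: shared edge appears in opposite
                    # directions in the two faces
                    if directed & other:
                        faces[fj] = faces[fj, ::-1]
                    visited[fj] = True
                    stack.append(fj)
    return faces


def connected_vertex_components(mesh: TriangleMesh) -> np.ndarray:
    """Component id per vertex from edge connectivity."""
    n_comp, labels = connected_components(mesh.vertex_adjacency().tocsr(), directed=False)
    return labels
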