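"""Frankfort coordinate-system alignment from Lp/Rp/Lo/G landmarks.

Canonical pose: origin at the porion midpoint, x-axis along Rp->Lp, the
plane through both porions and the left orbitale mapped to z=0, and the
glabella on the positive-y (anterior) side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh


class FrankfortError(ValueError):
    """Raised when the four reference landmarks are degenerate."""


@dataclass
class RigidTransform:
    """p -> R @ p + t with det(R) = +1."""

    R: np.ndarray
    t: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(p) = self(other(p))."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)


def frankfort_frame(Lp: np.ndarray, Rp: np.ndarray, Lo: np.ndarray,
                    G: np.ndarray) -> RigidTransform:
    """Rigid transform carrying landmark space into the Frankfort frame."""
    Lp, Rp, Lo, G = (np.asarray(p, dtype=float) for p in (Lp, Rp, Lo, G))
    for name, p in (("Lp", Lp), ("Rp", Rp), ("Lo", Lo), ("G", G)):
        if not np.all(np.isfinite(p)):
            raise FrankfortError(f"landmark {name} is not finite")
    origin = 0.5 * (Lp + Rp)
    x_axis = Lp - Rp
    nx = np.linalg.norm(x_axis)
    if nx < 1e-12:
        raise FrankfortError("Lp and Rp coincide")
    x_axis = x_axis / nx
    in_plane = Lo - origin
    z_axis = np.cross(x_axis, in_plane)
    nz = np.linalg.norm(z_axis)
    if nz < 1e-12 * max(nx, 1.0):
        raise FrankfortError("Lp, Rp, Lo are collinear")
    z_axis = z_axis / nz
    y_axis = np.cross(z_axis, x_axis)
    R = np.stack([x_axis, y_axis, z_axis])  # rows: world axes in new frame
    if (R @ (G - origin))[1] < 0:
        # flip y (and z to keep det=+1) so the glabella is anterior
        R = np.stack([x_axis, -y_axis, -z_axis])
    return RigidTransform(R, -R @ origin)


def frankfort_align(mesh: TriangleMesh, Lp, Rp, Lo, G) -> tuple[TriangleMesh, RigidTransform]:
    """Return the mesh expressed in the Frankfort frame and the transform used."""
    xf = frankfort_frame(Lp, Rp, Lo, G)
    out = TriangleMesh(
        xf.apply(mesh.vertices),
        mesh.faces.copy(),
        None if mesh.normals is None else mesh.normals @ xf.R.T,
    )
    return out, xf
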