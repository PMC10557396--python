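"""Synthetic paired skull/face cohorts with known ground truth.

The base head is a subdivided icosahedron of radius ~80 mm whose radial
function is modulated by low-order polynomial harmonics per specimen. The
face is the skull offset radially by a smooth per-specimen depth field;
nasal/oral patches are carved at fixed solid angles and carry a known
linear hard-to-soft covariation driven by shared latent factors. All
landmark analogues sit at fixed parametric directions, so cross-specimen
homology is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..meshkit.landmarks import (
    ComponentLabels,
    Configuration,
    LandmarkSet,
    facial_scheme_52,
)
from ..meshkit.mesh import TriangleMesh


class CohortError(ValueError):
    pass


# -- icosphere -----------------------------------------------------------


def icosphere(subdivisions: int = 3) -> TriangleMesh:
    """Unit icosphere; vertex order is deterministic per subdivision level."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []
        vlist = verts.tolist()

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in edge_mid:
                m = np.asarray(vlist[a]) + np.asarray(vlist[b])
                m /= np.linalg.norm(m)
                edge_mid[key] = len(vlist)
                vlist.append(m.tolist())
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.asarray(vlist)
        faces = np.asarray(new_faces, dtype=np.int64)
    return TriangleMesh(verts, faces)


# -- smooth scalar fields on the sphere ----------------------------------


def harmonic_basis(dirs: np.ndarray) -> np.ndarray:
    """Eight smooth low-order polynomial harmonics evaluated at unit dirs."""
    x, y, z = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    return np.stack(
        [
            x, y, z,
            x * y, y * z, x * z,
            x * x - y * y,
            3.0 * z * z - 1.0,
        ],
        axis=1,
    )


def _angles_to(dirs: np.ndarray, center: np.ndarray) -> np.ndarray:
    c = np.asarray(center, dtype=float)
    c = c / np.linalg.norm(c)
    return np.arccos(np.clip(dirs @ c, -1.0, 1.0))


def _bump(dirs: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    ang = _angles_to(dirs, center)
    sigma = radius / 2.5
    return np.exp(-0.5 * (ang / sigma) ** 2)


# -- cohort specification ------------------------------------------------

NOSE_CENTER = np.array([0.0, 0.85, 0.45]) / np.linalg.norm([0.0, 0.85, 0.45])
MOUTH_CENTER = np.array([0.0, 0.85, -0.45]) / np.linalg.norm([0.0, 0.85, -0.45])
NOSE_RADIUS = 0.30
MOUTH_RADIUS = 0.34


@dataclass
class CohortSpec:
    n: int = 48
    seed: int = 0
    subdivisions: int = 3
    base_radius: float = 80.0
    depth_mean: float = 9.0
    depth_pattern_amp: float = 2.0
    depth_subject_sd: float = 0.5       # per-subject scalar offset (mm)
    depth_field_sd: float = 0.0         # smooth per-subject field noise (mm)
    shape_mode_sd: float = 0.012        # SD of harmonic radius coefficients
    organ_latent_dim: int = 2
    organ_rho: float = 0.9              # shared-latent loading, in [0, 1]
    organ_hard_scale: float = 1.5       # mm
    organ_soft_scale: float = 1.5       # mm
    organ_noise_sd: float = 0.0         # independent soft-organ latent SD

    def __post_init__(self) -> None:
        if self.n < 3:
            raise CohortError("n must be >= 3")
        if not 0.0 <= self.organ_rho <= 1.0:
            raise CohortError("organ_rho must be in [0, 1]")
        for name in ("depth_subject_sd", "depth_field_sd", "shape_mode_sd",
                     "organ_noise_sd"):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be >= 0")
        if self.subdivisions < 2:
            raise CohortError("subdivisions < 2 cannot resolve the organ patches")


# -- landmark schemes at fixed directions --------------------------------


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


SKULL_LANDMARK_DIRECTIONS: dict[str, np.ndarray] = {
    "Lp": _unit([1.0, 0.0, 0.0]),
    "Rp": _unit([-1.0, 0.0, 0.0]),
    "Lo": _unit([0.6, 0.8, 0.0]),
    "G": _unit([0.0, 0.75, 0.66]),
}
# extra skull landmarks for registration constraints: a deterministic
# Fibonacci-sphere spread (the real scheme has 91 landmarks; density matters
# for the TPS stage of the hybrid registration)
_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))
for _i in range(44):
    _zc = 1.0 - 2.0 * (_i + 0.5) / 44.0
    _r = np.sqrt(max(0.0, 1.0 - _zc * _zc))
    _th = _GOLDEN * _i
    SKULL_LANDMARK_DIRECTIONS[f"S{_i + 1:02d}"] = _unit(
        [_r * np.cos(_th), _r * np.sin(_th), _zc]
    )


def _facial_landmark_directions() -> dict[str, np.ndarray]:
    """The 52-name facial scheme at fixed parametric directions."""
    out: dict[str, np.ndarray] = {}
    median = [
        ("Nasal bridge", [0.0, 0.86, 0.52]),
        ("Middle of nose", [0.0, 0.92, 0.40]),
        ("Tip of nose", [0.0, 0.97, 0.26]),
        ("Subnasale", [0.0, 0.99, 0.13]),
        ("Middle of cupid's bow upper lip", [0.0, 1.0, 0.0]),
        ("Middle of oral fissure", [0.0, 0.99, -0.12]),
        ("Middle of bottom lip", [0.0, 0.97, -0.24]),
        ("Tip of chin", [0.0, 0.87, -0.50]),
    ]
    for name, d in median:
        out[name] = _unit(d)
    bilateral = [
        ("Medial canthus", [0.18, 0.85, 0.50]),
        ("Lateral canthus", [0.42, 0.76, 0.50]),
        ("External alar curvature", [0.17, 0.95, 0.26]),
        ("Superior alar curvature", [0.14, 0.94, 0.32]),
        ("Alare", [0.19, 0.96, 0.21]),
        ("Alar curvature point", [0.16, 0.97, 0.16]),
        ("Corner of mouth", [0.25, 0.95, -0.12]),
        ("Crista philtra", [0.08, 0.99, 0.02]),
        ("Otobasion superius", [0.97, 0.05, 0.23]),
        ("Superior auricle", [0.95, 0.05, 0.31]),
        ("Posterior auricle", [0.99, -0.13, 0.08]),
        ("Inferior auricle", [0.98, 0.02, -0.19]),
        ("Anterior cymba concha", [0.97, 0.20, 0.12]),
        ("Superior cymba concha", [0.97, 0.16, 0.19]),
        ("Posterior concha", [0.99, -0.06, 0.10]),
        ("Intertragic incisure", [0.98, 0.17, -0.04]),
        ("Incisura intertragica", [0.98, 0.15, -0.10]),
        ("Tragion", [0.97, 0.22, 0.04]),
        ("Medial concha", [0.99, 0.10, 0.08]),
        ("Superior cavum concha", [0.98, 0.12, 0.15]),
        ("Otobasion posterius", [0.99, -0.16, 0.01]),
        ("Otobasion inferius", [0.98, -0.04, -0.14]),
    ]
    for name, d in bilateral:
        d = np.asarray(d, dtype=float)
        out[f"{name} (L)"] = _unit(d)
        out[f"{name} (R)"] = _unit(d * np.array([-1.0, 1.0, 1.0]))
    assert set(out) == set(facial_scheme_52())
    return out


FACIAL_LANDMARK_DIRECTIONS = _facial_landmark_directions()


# -- generator -----------------------------------------------------------


@dataclass
class CohortTruth:
    """Generator-side ground truth, aligned with the emitted meshes."""

    depth_fields: np.ndarray        # (n, k) true radial depths per vertex (mm)
    latent_hard: np.ndarray         # (n, q) shared latent factors z
    latent_soft_nose: np.ndarray    # (n, q) rho*z + sigma_o*w for the nose
    latent_soft_mouth: np.ndarray   # (n, q)
    nose_hard_modes: np.ndarray     # (q, k) radial hard displacement fields
    nose_soft_modes: np.ndarray     # (q, k)
    mouth_hard_modes: np.ndarray
    mouth_soft_modes: np.ndarray
    shape_coefficients: np.ndarray  # (n, 8) harmonic radius coefficients


@dataclass
class Cohort:
    spec: CohortSpec
    template: TriangleMesh          # unit icosphere (shared topology)
    directions: np.ndarray          # (k, 3) radial unit vectors
    skulls: list[TriangleMesh]
    faces: list[TriangleMesh]
    skull_landmarks: list[LandmarkSet]
    face_landmarks: list[LandmarkSet]
    skull_labels: ComponentLabels   # envelope / nasal / oral
    face_labels: ComponentLabels    # envelope / nose / mouth
    truth: CohortTruth
    organ_landmark_indices: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.skulls)

    @property
    def k(self) -> int:
        return self.template.n_vertices

    def organ_vertex_indices(self, organ: str) -> np.ndarray:
        """Template vertex indices of an organ patch, landmarks first."""
        label = {"nose": "nose", "mouth": "mouth"}[organ]
        patch = np.flatnonzero(self.face_labels.mask(label))
        lead = self.organ_landmark_indices[organ]
        rest = np.setdiff1d(patch, lead)
        return np.concatenate([lead, rest])

    def organ_config(self, i: int, organ: str, tissue: str) -> Configuration:
        """Hard (skull) or soft (face) organ configuration of specimen ``i``."""
        idx = self.organ_vertex_indices(organ)
        mesh = self.skulls[i] if tissue == "hard" else self.faces[i]
        return Configuration(
            mesh.vertices[idx],
            n_landmarks=len(self.organ_landmark_indices[organ]),
        )


def _organ_modes(dirs: np.ndarray, center: np.ndarray, radius: float,
                 q: int) -> np.ndarray:
    """q smooth radial displacement fields supported on one patch."""
    bump = _bump(dirs, center, radius)
    x = dirs[:, 0]
    z = dirs[:, 2]
    shapes = [bump, bump * 3.0 * x, bump * 3.0 * z, bump * 9.0 * x * z]
    if q > len(shapes):
        raise CohortError(f"organ_latent_dim must be <= {len(shapes)}")
    return np.stack(shapes[:q])


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Deterministically generate a paired skull/face cohort from a spec."""
    rng = np.random.default_rng(spec.seed)
    template = icosphere(spec.subdivisions)
    dirs = template.vertices  # unit
    k = len(dirs)

    nose_ang = _angles_to(dirs, NOSE_CENTER)
    mouth_ang = _angles_to(dirs, MOUTH_CENTER)
    nose_mask = nose_ang < NOSE_RADIUS
    mouth_mask = mouth_ang < MOUTH_RADIUS
    if nose_mask.sum() < 6 or mouth_mask.sum() < 6:
        raise CohortError(
            "mesh resolution too low to resolve the nasal/oral patches"
        )
    if np.any(nose_mask & mouth_mask):  # pragma: no cover - fixed geometry
        raise CohortError("organ patches overlap")

    skull_labels = np.array(["envelope"] * k, dtype=object)
    skull_labels[nose_mask] = "nasal"
    skull_labels[mouth_mask] = "oral"
    face_labels = np.array(["envelope"] * k, dtype=object)
    face_labels[nose_mask] = "nose"
    face_labels[mouth_mask] = "mouth"

    B = harmonic_basis(dirs)                       # (k, 8)
    pattern = dirs[:, 2] ** 2 - 1.0 / 3.0          # smooth, zero-mean-ish
    q = spec.organ_latent_dim
    nose_hard = _organ_modes(dirs, NOSE_CENTER, NOSE_RADIUS, q)
    nose_soft = _organ_modes(dirs, NOSE_CENTER, NOSE_RADIUS * 1.1, q)
    mouth_hard = _organ_modes(dirs, MOUTH_CENTER, MOUTH_RADIUS, q)
    mouth_soft = _organ_modes(dirs, MOUTH_CENTER, MOUTH_RADIUS * 1.1, q)

    coeffs = rng.normal(0.0, spec.shape_mode_sd, size=(spec.n, B.shape[1]))
    subj_offset = rng.normal(0.0, spec.depth_subject_sd, size=spec.n)
    field_coef = rng.normal(0.0, spec.depth_field_sd, size=(spec.n, B.shape[1]))
    z = rng.normal(0.0, 1.0, size=(spec.n, q))
    w_nose = rng.normal(0.0, 1.0, size=(spec.n, q))
    w_mouth = rng.normal(0.0, 1.0, size=(spec.n, q))
    rho = spec.organ_rho
    soft_nose_latent = rho * z + spec.organ_noise_sd * w_nose
    soft_mouth_latent = rho * z + spec.organ_noise_sd * w_mouth

    skulls, faces = [], []
    skull_lms, face_lms = [], []
    depth_fields = np.empty((spec.n, k))
    lm_skull_names = list(SKULL_LANDMARK_DIRECTIONS)
    lm_skull_dirs = np.stack([SKULL_LANDMARK_DIRECTIONS[n] for n in lm_skull_names])
    lm_face_names = list(FACIAL_LANDMARK_DIRECTIONS)
    lm_face_dirs = np.stack([FACIAL_LANDMARK_DIRECTIONS[n] for n in lm_face_names])

    for i in range(spec.n):
        def skull_radius(d: np.ndarray) -> np.ndarray:
            r = spec.base_radius * (1.0 + harmonic_basis(d) @ coeffs[i])
            r = r + spec.organ_hard_scale * (
                z[i] @ _organ_modes(d, NOSE_CENTER, NOSE_RADIUS, q)
            )
            r = r + spec.organ_hard_scale * (
                z[i] @ _organ_modes(d, MOUTH_CENTER, MOUTH_RADIUS, q)
            )
            return r

        def depth(d: np.ndarray) -> np.ndarray:
            dd = (
                spec.depth_mean
                + spec.depth_pattern_amp * (d[:, 2] ** 2 - 1.0 / 3.0)
                + subj_offset[i]
                + harmonic_basis(d) @ field_coef[i]
            )
            # the soft surface rides on the envelope, not on the hard organ
            # bumps: cancel them so soft patch shape is driven only by the
            # soft latent factors
            dd = dd - spec.organ_hard_scale * (
                z[i] @ _organ_modes(d, NOSE_CENTER, NOSE_RADIUS, q)
            )
            dd = dd - spec.organ_hard_scale * (
                z[i] @ _organ_modes(d, MOUTH_CENTER, MOUTH_RADIUS, q)
            )
            dd = dd + spec.organ_soft_scale * (
                soft_nose_latent[i] @ _organ_modes(d, NOSE_CENTER, NOSE_RADIUS * 1.1, q)
            )
            dd = dd + spec.organ_soft_scale * (
                soft_mouth_latent[i] @ _organ_modes(d, MOUTH_CENTER, MOUTH_RADIUS * 1.1, q)
            )
            return dd

        r_sk = skull_radius(dirs)
        d_fd = depth(dirs)
        if np.any(d_fd <= 0.25):
            raise CohortError(
                "depth field reaches <= 0.25 mm; face would intersect skull "
                "(reduce noise/organ scales)"
            )
        depth_fields[i] = d_fd
        skulls.append(TriangleMesh(r_sk[:, None] * dirs, template.faces.copy()))
        faces.append(
            TriangleMesh((r_sk + d_fd)[:, None] * dirs, template.faces.copy())
        )
        r_lm_sk = skull_radius(lm_skull_dirs)
        skull_lms.append(
            LandmarkSet(lm_skull_names, r_lm_sk[:, None] * lm_skull_dirs)
        )
        r_lm_face = skull_radius(lm_face_dirs) + depth(lm_face_dirs)
        face_lms.append(
            LandmarkSet(lm_face_names, r_lm_face[:, None] * lm_face_dirs)
        )

    # organ "landmark" analogues: a fixed, spread subset of each patch
    organ_lm = {}
    for organ, mask in (("nose", nose_mask), ("mouth", mouth_mask)):
        patch = np.flatnonzero(mask)
        take = min(8, len(patch))
        sel = patch[np.linspace(0, len(patch) - 1, take).round().astype(int)]
        organ_lm[organ] = np.unique(sel)

    truth = CohortTruth(
        depth_fields=depth_fields,
        latent_hard=z,
        latent_soft_nose=soft_nose_latent,
        latent_soft_mouth=soft_mouth_latent,
        nose_hard_modes=spec.organ_hard_scale * nose_hard,
        nose_soft_modes=spec.organ_soft_scale * nose_soft,
        mouth_hard_modes=spec.organ_hard_scale * mouth_hard,
        mouth_soft_modes=spec.organ_soft_scale * mouth_soft,
        shape_coefficients=coeffs,
    )
    return Cohort(
        spec=spec,
        template=template,
        directions=dirs,
        skulls=skulls,
        faces=faces,
        skull_landmarks=skull_lms,
        face_landmarks=face_lms,
        skull_labels=ComponentLabels(skull_labels),
        face_labels=ComponentLabels(face_labels),
        truth=truth,
        organ_landmark_indices=organ_lm,
    )
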