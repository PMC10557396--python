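"""Persist synthetic cohorts in the same formats the pipeline consumes."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..meshkit.io import read_labels_csv, read_mesh, write_labels_csv, write_mesh
from ..meshkit.landmarks import ComponentLabels, read_landmarks, write_landmarks
from .cohort import Cohort, CohortSpec, CohortTruth, icosphere


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write PLY meshes, landmark CSVs, label CSVs and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n": cohort.n,
        "seed": cohort.spec.seed,
        "subdivisions": cohort.spec.subdivisions,
        "organ_landmark_indices": {
            k: [int(i) for i in v] for k, v in cohort.organ_landmark_indices.items()
        },
        "specimens": [],
    }
    write_labels_csv(out / "skull_labels.csv", cohort.skull_labels.labels)
    write_labels_csv(out / "face_labels.csv", cohort.face_labels.labels)
    for i in range(cohort.n):
        stem = f"specimen_{i:03d}"
        write_mesh(cohort.skulls[i], out / f"{stem}_skull.ply")
        write_mesh(cohort.faces[i], out / f"{stem}_face.ply")
        write_landmarks(out / f"{stem}_skull_landmarks.csv", cohort.skull_landmarks[i])
        write_landmarks(out / f"{stem}_face_landmarks.csv", cohort.face_landmarks[i])
        manifest["specimens"].append(stem)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def load_cohort(in_dir: str | Path) -> Cohort:
    """Load a saved cohort; generator ground truth is not persisted."""
    src = Path(in_dir)
    with open(src / "manifest.json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    template = icosphere(manifest["subdivisions"])
    skulls, faces, skull_lms, face_lms = [], [], [], []
    for stem in manifest["specimens"]:
        skulls.append(read_mesh(src / f"{stem}_skull.ply"))
        faces.append(read_mesh(src / f"{stem}_face.ply"))
        skull_lms.append(read_landmarks(src / f"{stem}_skull_landmarks.csv"))
        face_lms.append(read_landmarks(src / f"{stem}_face_landmarks.csv"))
    k = template.n_vertices
    skull_labels = ComponentLabels(read_labels_csv(src / "skull_labels.csv", k))
    face_labels = ComponentLabels(read_labels_csv(src / "face_labels.csv", k))
    empty = np.zeros((0, 0))
    truth = CohortTruth(
        depth_fields=empty, latent_hard=empty, latent_soft_nose=empty,
        latent_soft_mouth=empty, nose_hard_modes=empty, nose_soft_modes=empty,
        mouth_hard_modes=empty, mouth_soft_modes=empty, shape_coefficients=empty,
    )
    return Cohort(
        spec=CohortSpec(n=manifest["n"], seed=manifest["seed"],
                        subdivisions=manifest["subdivisions"]),
        template=template,
        directions=template.vertices,
        skulls=skulls,
        faces=faces,
        skull_landmarks=skull_lms,
        face_landmarks=face_lms,
        skull_labels=skull_labels,
        face_labels=face_labels,
        truth=truth,
        organ_landmark_indices={
            key: np.asarray(v, dtype=np.int64)
            for key, v in manifest["organ_landmark_indices"].items()
        },
    )
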