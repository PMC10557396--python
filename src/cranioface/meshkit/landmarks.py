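"""Named landmark sets, landmark schemes and ordered point configurations."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import read_points_csv, write_points_csv


class LandmarkError(ValueError):
    """Raised for invalid landmark data (duplicates, unknown names, ...)."""


#: Median facial landmark names (8).
FACIAL_MEDIAN_NAMES: tuple[str, ...] = (
    "Nasal bridge",
    "Middle of nose",
    "Tip of nose",
    "Subnasale",
    "Middle of cupid's bow upper lip",
    "Middle of oral fissure",
    "Middle of bottom lip",
    "Tip of chin",
)

#: Bilateral facial landmark base names (22); each occurs with (L)/(R) suffixes.
FACIAL_BILATERAL_NAMES: tuple[str, ...] = (
    "Medial canthus",
    "Lateral canthus",
    "External alar curvature",
    "Superior alar curvature",
    "Alare",
    "Alar curvature point",
    "Corner of mouth",
    "Crista philtra",
    "Otobasion superius",
    "Superior auricle",
    "Posterior auricle",
    "Inferior auricle",
    "Anterior cymba concha",
    "Superior cymba concha",
    "Posterior concha",
    "Intertragic incisure",
    "Incisura intertragica",
    "Tragion",
    "Medial concha",
    "Superior cavum concha",
    "Otobasion posterius",
    "Otobasion inferius",
)

#: Skull landmark names that carry semantics (Frankfort frame definition).
REQUIRED_SKULL_NAMES: tuple[str, ...] = ("Lp", "Rp", "Lo", "G")


def facial_scheme_52() -> tuple[str, ...]:
    """The 52-name facial scheme: 8 median + 22 bilateral pairs."""
    names = list(FACIAL_MEDIAN_NAMES)
    for base in FACIAL_BILATERAL_NAMES:
        names.append(f"{base} (L)")
        names.append(f"{base} (R)")
    return tuple(names)


def skull_scheme(extra_names: tuple[str, ...] = ()) -> tuple[str, ...]:
    """Configurable skull scheme: Lp/Rp/Lo/G plus arbitrary extra names."""
    names = list(REQUIRED_SKULL_NAMES) + [
        n for n in extra_names if n not in REQUIRED_SKULL_NAMES
    ]
    return tuple(names)


@dataclass
class LandmarkSet:
    """Ordered named 3D points (mm)."""

    names: list[str]
    points: np.ndarray

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.names) != len(self.points):
            raise LandmarkError("name/point count mismatch")
        seen = set()
        for n in self.names:
            if n in seen:
                raise LandmarkError(f"duplicate landmark name: {n!r}")
            seen.add(n)

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def subset(self, names: list[str]) -> "LandmarkSet":
        idx = [self.names.index(n) for n in names]
        return LandmarkSet(list(names), self.points[idx])

    def validate_scheme(self, scheme: tuple[str, ...]) -> None:
        unknown = [n for n in self.names if n not in scheme]
        if unknown:
            raise LandmarkError(f"unknown landmark names: {unknown}")

    @property
    def median_names(self) -> list[str]:
        return [n for n in self.names if not (n.endswith("(L)") or n.endswith("(R)"))]

    @property
    def bilateral_names(self) -> list[str]:
        return [n for n in self.names if n.endswith("(L)") or n.endswith("(R)")]


def read_landmarks(path: str | Path, scheme: tuple[str, ...] | None = None,
                   strict: bool = False) -> LandmarkSet:
    """Read a ``name,x,y,z`` landmark CSV, preserving row order.

    With ``strict`` and a scheme, names outside the scheme raise
    :class:`LandmarkError` listing the offenders.
    """
    names, pts = read_points_csv(path)
    lm = LandmarkSet(names, pts)
    if strict and scheme is not None:
        lm.validate_scheme(scheme)
    return lm


def write_landmarks(path: str | Path, landmarks: LandmarkSet) -> None:
    write_points_csv(path, landmarks.names, landmarks.points)


@dataclass
class Configuration:
    """Ordered k x 3 landmark+semilandmark matrix in fixed correspondence.

    ``n_landmarks`` rows of named landmarks come first, followed by
    ``n_semilandmarks`` sampled points; the ordering is identical across
    every specimen of a cohort.
    """

    points: np.ndarray
    n_landmarks: int = 0
    n_semilandmarks: int = field(default=-1)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.n_semilandmarks < 0:
            self.n_semilandmarks = len(self.points) - self.n_landmarks
        if self.n_landmarks + self.n_semilandmarks != len(self.points):
            raise LandmarkError("landmark/semilandmark counts do not sum to k")

    @property
    def k(self) -> int:
        return len(self.points)

    def copy(self) -> "Configuration":
        return Configuration(self.points.copy(), self.n_landmarks, self.n_semilandmarks)

    def flat(self) -> np.ndarray:
        return self.points.reshape(-1)

    @classmethod
    def from_parts(cls, landmarks: np.ndarray | None,
                   semilandmarks: np.ndarray | None) -> "Configuration":
        parts = []
        nl = ns = 0
        if landmarks is not None and len(landmarks):
            parts.append(np.asarray(landmarks, dtype=float).reshape(-1, 3))
            nl = len(parts[-1])
        if semilandmarks is not None and len(semilandmarks):
            parts.append(np.asarray(semilandmarks, dtype=float).reshape(-1, 3))
            ns = len(parts[-1])
        if not parts:
            raise LandmarkError("empty configuration")
        return cls(np.concatenate(parts), nl, ns)


@dataclass
class ComponentLabels:
    """Per-vertex component labels over a template mesh.

    Labels are strings from a fixed vocabulary (e.g. ``envelope``, ``nasal``,
    ``oral`` on skulls; ``envelope``, ``nose``, ``mouth`` on faces);
    ``excluded`` marks vertices outside every component.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def mask(self, component: str) -> np.ndarray:
        return self.labels == component

    def components(self) -> list[str]:
        return sorted(set(self.labels.tolist()) - {"excluded"})

    def __len__(self) -> int:
        return len(self.labels)
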