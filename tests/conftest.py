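import numpy as np
import pytest

from cranioface.meshkit import TriangleMesh
from cranioface.synthetic_data import CohortSpec, generate_cohort, icosphere


@pytest.fixture(scope="session")
def unit_sphere() -> TriangleMesh:
    return icosphere(3)


@pytest.fixture(scope="session")
def sphere80() -> TriangleMesh:
    base = icosphere(3)
    return TriangleMesh(80.0 * base.vertices, base.faces)


@pytest.fixture(scope="session")
def small_cohort():
    """8 specimens, 642 vertices, moderate variation and smooth depth noise."""
    return generate_cohort(
        CohortSpec(n=8, seed=7, subdivisions=3, shape_mode_sd=0.02,
                   depth_field_sd=0.1)
    )


@pytest.fixture(scope="session")
def quiet_cohort():
    """Zero noise, perfect hard/soft coupling: exact-recovery fixture."""
    return generate_cohort(
        CohortSpec(n=6, seed=3, subdivisions=3, shape_mode_sd=0.0,
                   depth_subject_sd=0.0, depth_field_sd=0.0,
                   organ_rho=1.0, organ_noise_sd=0.0)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
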