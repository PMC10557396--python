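import numpy as np
import pytest

from cranioface.assembly import (
    LaplacianError,
    PipelineError,
    PipelineSettings,
    SSMError,
    approximate_face,
    build_ssm,
    fit_ssm,
    laplacian_refine,
    match_loops,
    place_component,
    resample_loop,
    train_pipeline,
    transform_to_ssm_frame,
    uniform_laplacian,
)
from cranioface.meshkit import ComponentLabels, LandmarkSet, TriangleMesh
from cranioface.meshkit.frankfort import frankfort_frame
from cranioface.registration import SimilarityTransform
from cranioface.synthetic_data import icosphere

from conftest import random_rotation


SETTINGS = PipelineSettings(organ_eta=0.01)


def _trained(cohort, exclude=None):
    idx = [i for i in range(cohort.n) if i != exclude]
    return train_pipeline(
        [cohort.skulls[i] for i in idx],
        [cohort.faces[i] for i in idx],
        [cohort.skull_landmarks[i] for i in idx],
        cohort.skull_labels,
        cohort.face_labels,
        cohort.organ_landmark_indices,
        SETTINGS,
    )


class TestLoopResampling:
    def test_circle_resample_preserves_geometry(self):
        t = np.linspace(0, 2 * np.pi, 37, endpoint=False)
        loop = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        out = resample_loop(loop, 100)
        assert out.shape == (100, 3)
        r = np.linalg.norm(out, axis=1)
        np.testing.assert_allclose(r, 1.0, atol=0.01)

    def test_match_loops_recovers_similarity(self, rng):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        loop = np.column_stack([np.cos(t), 0.6 * np.sin(t), 0.1 * np.sin(2 * t)])
        R = random_rotation(rng)
        s = 1.7
        tvec = rng.normal(0, 2, 3)
        moved = s * np.roll(loop, 13, axis=0) @ R.T + tvec
        src, tgt, xf = match_loops(moved, loop, m=100)
        assert xf.S == pytest.approx(1 / s, rel=1e-3)
        rms = np.sqrt(np.mean(np.sum((xf.apply(src) - tgt) ** 2, axis=1)))
        assert rms < 1e-3


class TestPlaceComponent:
    def _setup(self, small_cohort):
        trained = _trained(small_cohort)
        organ = "nose"
        order = trained.organ_indices[organ]
        comp = TriangleMesh(trained.average_face.vertices[order],
                            trained.organ_faces[organ])
        return trained, comp, organ

    def test_component_in_place_identity(self, small_cohort):
        trained, comp, organ = self._setup(small_cohort)
        res = place_component(comp, trained.average_face,
                              trained.face_labels, organ)
        np.testing.assert_allclose(res.transform.R, np.eye(3), atol=1e-6)
        assert res.transform.S == pytest.approx(1.0, abs=1e-6)
        assert res.boundary_rms_after <= res.boundary_rms_before + 1e-12

    def test_scaled_translated_recovery(self, small_cohort):
        trained, comp, organ = self._setup(small_cohort)
        moved = TriangleMesh(0.5 * comp.vertices + np.array([3.0, -2.0, 5.0]),
                             comp.faces)
        res = place_component(moved, trained.average_face,
                              trained.face_labels, organ)
        assert res.transform.S == pytest.approx(2.0, rel=1e-6)
        np.testing.assert_allclose(res.placed_points, comp.vertices, atol=1e-6)
        assert res.boundary_rms_after < 1e-6

    def test_m_too_small_error(self, small_cohort):
        trained, comp, organ = self._setup(small_cohort)
        from cranioface.assembly import PlacementError

        with pytest.raises(PlacementError):
            place_component(comp, trained.average_face,
                            trained.face_labels, organ, m=2)

    def test_closed_component_error(self, small_cohort):
        trained, comp, organ = self._setup(small_cohort)
        sphere = icosphere(1)
        from cranioface.assembly import PlacementError

        with pytest.raises(PlacementError):
            place_component(sphere, trained.average_face,
                            trained.face_labels, organ)


class TestSSM:
    def test_identical_faces_mean(self, rng):
        face = rng.normal(0, 10, (20, 3))
        ssm = build_ssm([face.copy() for _ in range(4)])
        assert ssm.d == 0 or ssm.eigenvalues.max() < 1e-12
        centered = face - face.mean(axis=0)
        # mean equals that face up to the GPA's rigid alignment
        from cranioface.morphometrics import procrustes_distance
        assert procrustes_distance(ssm.mean_face, centered,
                                   with_scaling=False) < 1e-8

    def test_training_face_recovery_full_rank(self, rng):
        faces = [rng.normal(0, 5, (15, 3)) for _ in range(6)]
        ssm = build_ssm(faces, cumulative_threshold=1.0)
        rec = ssm.synthesize(ssm.scores[2])
        from cranioface.morphometrics import gpa
        aligned = gpa(faces, with_scaling=False).aligned[2]
        np.testing.assert_allclose(rec, aligned, atol=1e-6)

    def test_three_mode_population_variance(self, rng):
        k = 30
        modes = np.linalg.qr(rng.normal(size=(3 * k, 3)))[0].T
        mean = rng.normal(0, 5, 3 * k)
        lat = rng.normal(0, 1, (50, 3)) * [5.0, 3.0, 2.0]
        faces = [(mean + lat[i] @ modes).reshape(k, 3) for i in range(50)]
        ssm = build_ssm(faces, cumulative_threshold=1.0)
        top3 = ssm.eigenvalues[:3].sum() / ssm.eigenvalues.sum()
        assert top3 >= 0.95

    def test_synthesize_zero_is_mean(self, rng):
        ssm = build_ssm([rng.normal(0, 3, (10, 3)) for _ in range(5)])
        np.testing.assert_allclose(ssm.synthesize(np.zeros(ssm.d)), ssm.mean_face)

    def test_basis_orthonormal(self, rng):
        ssm = build_ssm([rng.normal(0, 3, (10, 3)) for _ in range(6)],
                        cumulative_threshold=1.0)
        np.testing.assert_allclose(ssm.basis @ ssm.basis.T, np.eye(ssm.d),
                                   atol=1e-8)

    def test_too_few_faces(self, rng):
        with pytest.raises(SSMError):
            build_ssm([rng.normal(size=(5, 3))] * 2)


@pytest.fixture(scope="module")
def ssm():
    rng = np.random.default_rng(0)
    return build_ssm([rng.normal(0, 5, (40, 3)) for _ in range(10)],
                     cumulative_threshold=1.0)


class TestFitSSM:

    def test_training_face_scores_recovered(self, ssm):
        target = ssm.synthesize(ssm.scores[3])
        pairs = [(target[i], i) for i in range(ssm.n_points)]
        beta, fitted = fit_ssm(ssm, pairs, lam=0.0)
        np.testing.assert_allclose(beta, ssm.scores[3], atol=1e-6)
        np.testing.assert_allclose(fitted, target, atol=1e-6)

    def test_lambda_infinity_collapses_to_mean(self, ssm, rng):
        pairs = [(rng.normal(0, 5, 3), i) for i in range(0, ssm.n_points, 3)]
        beta, fitted = fit_ssm(ssm, pairs, lam=1e9)
        np.testing.assert_allclose(beta, 0.0, atol=1e-8)
        np.testing.assert_allclose(fitted, ssm.mean_face, atol=1e-6)

    def test_partial_correspondence_recovery_vs_dense_oracle(self, ssm, rng):
        beta_true = rng.normal(0, 1, ssm.d) * np.sqrt(ssm.eigenvalues)
        face = ssm.synthesize(beta_true)
        sel = rng.choice(ssm.n_points, int(0.3 * ssm.n_points), replace=False)
        pairs = [(face[i], int(i)) for i in sel]
        lam = 1e-4
        beta, _ = fit_ssm(ssm, pairs, lam=lam)
        rel = np.linalg.norm(beta - beta_true) / np.linalg.norm(beta_true)
        assert rel < 0.05
        # dense normal-equation oracle on the same rows
        rows = np.concatenate([[3 * i, 3 * i + 1, 3 * i + 2] for i in sel])
        Us = ssm.basis[:, rows].T
        resid = np.concatenate([face[i] - ssm.mean_face[i] for i in sel])
        oracle = np.linalg.solve(Us.T @ Us + lam ** 2 * np.eye(ssm.d),
                                 Us.T @ resid)
        np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_objective_no_worse_than_zero(self, ssm, rng):
        pairs = [(rng.normal(0, 5, 3), int(i))
                 for i in rng.choice(ssm.n_points, 12, replace=False)]
        lam = 0.01
        beta, _ = fit_ssm(ssm, pairs, lam=lam)

        def objective(b):
            face = ssm.synthesize(b)
            return sum(np.sum((p - face[i]) ** 2) for p, i in pairs) + \
                lam ** 2 * np.sum(b ** 2)

        assert objective(beta) <= objective(np.zeros(ssm.d)) + 1e-9

    def test_linearity_of_synthesis(self, ssm, rng):
        b1 = rng.normal(0, 1, ssm.d)
        b2 = rng.normal(0, 1, ssm.d)
        lhs = ssm.synthesize(b1 + b2) - ssm.mean_face
        rhs = (ssm.synthesize(b1) - ssm.mean_face) + (ssm.synthesize(b2) - ssm.mean_face)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_empty_correspondences(self, ssm):
        with pytest.raises(SSMError):
            fit_ssm(ssm, [])


@pytest.fixture(scope="module")
def mesh():
    base = icosphere(2)
    return TriangleMesh(50.0 * base.vertices, base.faces)


class TestLaplacianRefine:

    def test_self_anchor_fixed_point(self, mesh, rng):
        sel = rng.choice(mesh.n_vertices, 30, replace=False)
        anchors = {int(i): mesh.vertices[i] for i in sel}
        out = laplacian_refine(mesh, anchors, anchor_weight=1.0)
        np.testing.assert_allclose(out.mesh.vertices, mesh.vertices, atol=1e-8)

    def test_translation_propagation(self, mesh, rng):
        sel = rng.choice(mesh.n_vertices, 25, replace=False)
        shift = np.array([3.0, 0.0, 0.0])
        anchors = {int(i): mesh.vertices[i] + shift for i in sel}
        out = laplacian_refine(mesh, anchors)
        np.testing.assert_allclose(out.mesh.vertices, mesh.vertices + shift,
                                   atol=1e-6)

    def test_matches_dense_solver(self, mesh, rng):
        sel = rng.choice(mesh.n_vertices, 15, replace=False)
        anchors = {int(i): mesh.vertices[i] + rng.normal(0, 2, 3) for i in sel}
        w = 2.5
        out = laplacian_refine(mesh, anchors, anchor_weight=w)
        L = uniform_laplacian(mesh).toarray()
        n = mesh.n_vertices
        S = np.zeros((len(sel), n))
        tgt = np.zeros((len(sel), 3))
        for r, (i, p) in enumerate(sorted(anchors.items())):
            S[r, i] = np.sqrt(w)
            tgt[r] = np.sqrt(w) * p
        A = np.vstack([L, S])
        b = np.vstack([L @ mesh.vertices, tgt])
        dense = np.linalg.solve(A.T @ A, A.T @ b)
        np.testing.assert_allclose(out.mesh.vertices, dense, atol=1e-8)

    def test_topology_preserved(self, mesh, rng):
        anchors = {0: mesh.vertices[0] + 1.0}
        out = laplacian_refine(mesh, anchors)
        assert out.mesh.n_vertices == mesh.n_vertices
        np.testing.assert_array_equal(out.mesh.faces, mesh.faces)

    def test_anchor_residual_decreases_with_weight(self, mesh, rng):
        sel = rng.choice(mesh.n_vertices, 10, replace=False)
        anchors = {int(i): mesh.vertices[i] + rng.normal(0, 3, 3) for i in sel}
        res = [laplacian_refine(mesh, anchors, anchor_weight=w).anchor_residual_max
               for w in (0.1, 1.0, 10.0, 1000.0)]
        assert all(a >= b - 1e-12 for a, b in zip(res, res[1:]))
        assert res[-1] < 0.01

    def test_no_anchor_error(self, mesh):
        with pytest.raises(LaplacianError):
            laplacian_refine(mesh, {})


class TestFrameTransfer:
    def test_self_transfer_identity(self, small_cohort):
        trained = _trained(small_cohort)
        env_idx = np.flatnonzero(trained.skull_labels.mask("envelope"))
        from cranioface.assembly.pipeline import _patch_faces

        env_mesh = TriangleMesh(
            trained.average_face.vertices[env_idx],
            _patch_faces(trained.template_faces, env_idx),
        )
        tr = transform_to_ssm_frame(
            trained.average_face.vertices, env_mesh, trained.average_face,
            trained.ssm, trained.average_skull.vertices, trained.directions,
        )
        # average face is GPA-registered to the SSM mean frame up to a small
        # rigid component; scale must be ~1
        assert tr.transform.S == pytest.approx(1.0, abs=0.01)
        assert len(tr.correspondences) > 0.7 * len(env_idx)

    def test_known_offset_recovered(self, small_cohort):
        trained = _trained(small_cohort)
        env_idx = np.flatnonzero(trained.skull_labels.mask("envelope"))
        from cranioface.assembly.pipeline import _patch_faces

        rngl = np.random.default_rng(1)
        R = random_rotation(rngl)
        t = rngl.normal(0, 20, 3)
        s = 1.3
        move = lambda pts: s * pts @ R.T + t  # noqa: E731
        env_mesh = TriangleMesh(
            move(trained.average_face.vertices[env_idx]),
            _patch_faces(trained.template_faces, env_idx),
        )
        avg_moved = TriangleMesh(move(trained.average_face.vertices),
                                 trained.template_faces)
        tr = transform_to_ssm_frame(
            move(trained.average_face.vertices), env_mesh, avg_moved,
            trained.ssm, move(trained.average_skull.vertices),
            (trained.directions @ R.T),
        )
        # recovered similarity undoes the offset: scale ~ 1/s
        assert tr.transform.S == pytest.approx(1.0 / s, rel=0.01)

    def test_too_few_rays_error(self, small_cohort):
        trained = _trained(small_cohort)
        tiny = icosphere(0)
        far = TriangleMesh(tiny.vertices + 1e5, tiny.faces)
        with pytest.raises(SSMError):
            transform_to_ssm_frame(
                trained.average_face.vertices, far, far, trained.ssm,
                trained.average_skull.vertices, trained.directions,
            )


class TestApproximateFace:
    def test_beats_mean_face_baseline(self, small_cohort):
        c = small_cohort
        test = 0
        trained = _trained(c, exclude=test)
        res = approximate_face(c.skulls[test], c.skull_landmarks[test], trained,
                               SETTINGS)
        lm = c.skull_landmarks[test]
        xf = frankfort_frame(lm["Lp"], lm["Rp"], lm["Lo"], lm["G"])
        actual = xf.apply(c.faces[test].vertices)
        err = np.linalg.norm(res.final_mesh.vertices - actual, axis=1).mean()
        base = np.linalg.norm(trained.average_face.vertices - actual, axis=1).mean()
        assert err < base

    def test_missing_landmark_error_names_stage(self, small_cohort):
        c = small_cohort
        trained = _trained(c, exclude=0)
        lm = c.skull_landmarks[0]
        names = [n for n in lm.names if n != "G"]
        broken = LandmarkSet(names, np.stack([lm[n] for n in names]))
        with pytest.raises(PipelineError, match="frankfort"):
            approximate_face(c.skulls[0], broken, trained, SETTINGS)

    def test_deterministic(self, small_cohort):
        c = small_cohort
        trained = _trained(c, exclude=1)
        a = approximate_face(c.skulls[1], c.skull_landmarks[1], trained, SETTINGS)
        b = approximate_face(c.skulls[1], c.skull_landmarks[1], trained, SETTINGS)
        np.testing.assert_array_equal(a.final_mesh.vertices, b.final_mesh.vertices)

    def test_rigid_equivariance(self, small_cohort):
        c = small_cohort
        trained = _trained(c, exclude=2)
        res0 = approximate_face(c.skulls[2], c.skull_landmarks[2], trained, SETTINGS)
        rngl = np.random.default_rng(3)
        R = random_rotation(rngl)
        t = rngl.normal(0, 30, 3)
        moved_skull = TriangleMesh(c.skulls[2].vertices @ R.T + t,
                                   c.skulls[2].faces)
        moved_lm = LandmarkSet(c.skull_landmarks[2].names,
                               c.skull_landmarks[2].points @ R.T + t)
        res1 = approximate_face(moved_skull, moved_lm, trained, SETTINGS)
        # both go through Frankfort alignment, so outputs coincide
        diff = np.linalg.norm(res0.final_mesh.vertices - res1.final_mesh.vertices,
                              axis=1)
        assert diff.max() < 1e-6
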