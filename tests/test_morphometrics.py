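import numpy as np
import pytest
from scipy.stats import kstest

from cranioface.morphometrics import (
    PCAError,
    PLSError,
    ProcrustesError,
    centroid_size,
    gpa,
    pca_shapes,
    pls_extreme_shapes,
    pls_permutation_test,
    procrustes_distance,
    rv_coefficient,
    two_block_pls,
)

from conftest import random_rotation


def _similarity(rng, config, scale=True):
    R = random_rotation(rng)
    s = rng.uniform(0.5, 2.0) if scale else 1.0
    t = rng.normal(0, 10, 3)
    return s * config @ R.T + t


class TestGPA:
    def test_identical_configs_zero_distance(self, rng):
        c = rng.normal(0, 10, (12, 3))
        res = gpa([c, c.copy()])
        np.testing.assert_allclose(res.distances, 0.0, atol=1e-10)

    def test_similarity_invariance(self, rng):
        c = rng.normal(0, 10, (15, 3))
        res = gpa([c, _similarity(rng, c)], with_scaling=True)
        assert res.distances.max() < 1e-10

    def test_rigid_only_without_scaling(self, rng):
        c = rng.normal(0, 10, (15, 3))
        rigid = _similarity(rng, c, scale=False)
        res = gpa([c, rigid], with_scaling=False)
        assert res.distances.max() < 1e-9
        scaled = 1.5 * c
        res2 = gpa([c, scaled], with_scaling=False)
        assert res2.distances.max() > 0.1

    def test_unit_centroid_size(self, rng):
        configs = [rng.normal(0, 10, (10, 3)) for _ in range(5)]
        res = gpa(configs, with_scaling=True)
        for a in res.aligned:
            assert centroid_size(a) == pytest.approx(1.0, abs=1e-9)

    def test_mean_is_average_of_aligned(self, rng):
        configs = [rng.normal(0, 10, (10, 3)) for _ in range(6)]
        res = gpa(configs)
        np.testing.assert_allclose(res.mean_shape, res.aligned.mean(axis=0),
                                   atol=1e-9)

    def test_input_invariance_of_result(self, rng):
        configs = [rng.normal(0, 10, (10, 3)) for _ in range(4)]
        res1 = gpa(configs, with_scaling=True)
        moved = [_similarity(rng, c) for c in configs]
        res2 = gpa(moved, with_scaling=True)
        np.testing.assert_allclose(np.sort(res1.distances), np.sort(res2.distances),
                                   atol=1e-8)

    def test_degenerate_config_error(self, rng):
        with pytest.raises(ProcrustesError):
            gpa([np.zeros((5, 3)), rng.normal(size=(5, 3))])

    def test_mismatched_k_error(self, rng):
        with pytest.raises(ProcrustesError):
            gpa([rng.normal(size=(5, 3)), rng.normal(size=(6, 3))])


class TestProcrustesDistance:
    def test_zero_for_identical(self, rng):
        c = rng.normal(0, 10, (8, 3))
        assert procrustes_distance(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(10):
            a = rng.normal(0, 10, (9, 3))
            b = rng.normal(0, 10, (9, 3))
            assert procrustes_distance(a, b) == pytest.approx(
                procrustes_distance(b, a), abs=1e-12
            )

    def test_matches_pairwise_gpa(self, rng):
        """Closed form equals the inter-configuration distance of a 2-shape GPA."""
        for _ in range(10):
            a = rng.normal(0, 10, (10, 3))
            b = rng.normal(0, 10, (10, 3))
            d_closed = procrustes_distance(a, b, with_scaling=True)
            res = gpa([a, b], with_scaling=True)
            d_gpa = float(np.linalg.norm(res.aligned[0] - res.aligned[1]))
            assert d_closed == pytest.approx(d_gpa, abs=1e-8)

    def test_triangle_inequality_empirical(self, rng):
        for _ in range(30):
            a, b, c = (rng.normal(0, 5, (7, 3)) for _ in range(3))
            dab = procrustes_distance(a, b)
            dbc = procrustes_distance(b, c)
            dac = procrustes_distance(a, c)
            assert dac <= dab + dbc + 1e-9

    def test_invariance_to_similarity(self, rng):
        a = rng.normal(0, 10, (12, 3))
        b = rng.normal(0, 10, (12, 3))
        d0 = procrustes_distance(a, b)
        d1 = procrustes_distance(_similarity(rng, a), _similarity(rng, b))
        assert d0 == pytest.approx(d1, abs=1e-10)


class TestShapePCA:
    def test_rank_two_plane(self, rng):
        base = rng.normal(0, 1, (3, 30))
        mean = rng.normal(0, 5, 30)
        X = mean + rng.normal(0, 1, (20, 2)) @ base[:2]
        space = pca_shapes(X.reshape(20, 10, 3), cumulative_threshold=1.0)
        assert space.d == 2

    def test_lossless_reconstruction_threshold_one(self, rng):
        X = rng.normal(0, 2, (10, 8, 3))
        space = pca_shapes(X, cumulative_threshold=1.0)
        for i in range(10):
            rec = space.reconstruct(space.scores[i])
            np.testing.assert_allclose(rec, X[i].reshape(8, 3), atol=1e-6)

    def test_reconstruction_error_equals_discarded_mass(self, rng):
        X = rng.normal(0, 2, (15, 10, 3))
        space = pca_shapes(X, cumulative_threshold=0.7)
        Xc = X.reshape(15, -1) - X.reshape(15, -1).mean(axis=0)
        err = 0.0
        for i in range(15):
            rec = space.reconstruct(space.scores[i]).reshape(-1)
            err += np.sum((rec - (X[i].reshape(-1))) ** 2)
        discarded = (space.total_variance - space.eigenvalues.sum()) * (15 - 1)
        assert err == pytest.approx(discarded, rel=1e-8)

    def test_basis_orthonormal(self, rng):
        space = pca_shapes(rng.normal(0, 1, (12, 9, 3)))
        np.testing.assert_allclose(space.basis @ space.basis.T,
                                   np.eye(space.d), atol=1e-8)

    def test_eigenvalues_non_increasing(self, rng):
        space = pca_shapes(rng.normal(0, 1, (12, 9, 3)), cumulative_threshold=1.0)
        assert np.all(np.diff(space.eigenvalues) <= 1e-12)

    def test_generator_variance_recovery(self, rng):
        # 3 orthogonal factors with known variances
        k = 40
        basis = np.linalg.qr(rng.normal(size=(3 * k, 3)))[0].T  # (3, 3k)
        sds = np.array([3.0, 2.0, 1.0])
        scores = rng.normal(0, 1, (300, 3)) * sds
        X = (scores @ basis).reshape(300, k, 3)
        space = pca_shapes(X, cumulative_threshold=1.0)
        np.testing.assert_allclose(space.eigenvalues[:3], sds ** 2, rtol=0.15)

    def test_bad_threshold(self, rng):
        with pytest.raises(PCAError):
            pca_shapes(rng.normal(size=(5, 4, 3)), cumulative_threshold=1.5)

    def test_too_few_specimens(self, rng):
        with pytest.raises(PCAError):
            pca_shapes(rng.normal(size=(2, 4, 3)))


class TestTwoBlockPLS:
    def test_identical_blocks_axis1_correlation(self, rng):
        X = rng.normal(0, 1, (30, 6))
        res = two_block_pls(X, X)
        assert res.correlations[0] == pytest.approx(1.0, abs=1e-10)
        assert res.pct_covariance[0] == res.pct_covariance.max()

    def test_matches_dense_svd_oracle(self, rng):
        """Axes/correlations match an independent dense SVD of the
        cross-covariance, up to sign."""
        for _ in range(50):
            n, p1, p2 = 20, 7, 5
            X = rng.normal(0, 1, (n, p1))
            Y = rng.normal(0, 1, (n, p2))
            res = two_block_pls(X, Y)
            Xc = X - X.mean(axis=0)
            Yc = Y - Y.mean(axis=0)
            U, s, Vt = np.linalg.svd(Xc.T @ Yc / (n - 1), full_matrices=False)
            np.testing.assert_allclose(res.singular_values, s[: res.n_axes],
                                       atol=1e-10)
            for j in range(res.n_axes):
                dot = abs(float(res.u[:, j] @ U[:, j]))
                assert dot == pytest.approx(1.0, abs=1e-8)
                # oracle correlation for the axis
                s1 = Xc @ U[:, j]
                s2 = Yc @ Vt[j]
                r = np.corrcoef(s1, s2)[0, 1]
                assert abs(res.correlations[j]) == pytest.approx(abs(r), abs=1e-8)

    def test_pct_covariance_sums_to_100(self, rng):
        res = two_block_pls(rng.normal(0, 1, (15, 6)), rng.normal(0, 1, (15, 4)))
        assert res.pct_covariance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_independent_blocks_low_correlation(self, rng):
        hits = 0
        runs = 40
        for _ in range(runs):
            X = rng.normal(0, 1, (100, 2))
            Y = rng.normal(0, 1, (100, 2))
            res = two_block_pls(X, Y)
            if abs(res.correlations[0]) < 0.3:
                hits += 1
        assert hits >= 0.9 * runs

    def test_n_too_small(self, rng):
        with pytest.raises(PLSError):
            two_block_pls(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestRV:
    def test_self_rv_is_one(self, rng):
        X = rng.normal(0, 1, (10, 4))
        assert rv_coefficient(X, X) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_rotation_invariance(self, rng):
        X = rng.normal(0, 1, (12, 5))
        O = np.linalg.qr(rng.normal(size=(5, 5)))[0]
        assert rv_coefficient(X, X @ O) == pytest.approx(1.0, abs=1e-10)

    def test_trace_formula_oracle(self, rng):
        X = rng.normal(0, 1, (5, 3))
        Y = rng.normal(0, 1, (5, 3))
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        sxy = Xc.T @ Yc
        expected = np.trace(sxy @ sxy.T) / np.sqrt(
            np.trace((Xc.T @ Xc) @ (Xc.T @ Xc)) * np.trace((Yc.T @ Yc) @ (Yc.T @ Yc))
        )
        assert rv_coefficient(X, Y) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        X = rng.normal(0, 1, (8, 4))
        Y = rng.normal(0, 1, (8, 6))
        assert rv_coefficient(X, Y) == pytest.approx(rv_coefficient(Y, X), abs=1e-12)

    def test_range(self, rng):
        for _ in range(20):
            v = rv_coefficient(rng.normal(size=(7, 3)), rng.normal(size=(7, 4)))
            assert 0.0 <= v <= 1.0

    def test_zero_variance_error(self, rng):
        with pytest.raises(PLSError):
            rv_coefficient(np.ones((5, 3)), rng.normal(size=(5, 3)))


class TestPermutationTest:
    def test_min_p_value(self, rng):
        X = rng.normal(0, 1, (20, 4))
        Y = X + rng.normal(0, 0.01, (20, 4))
        res = pls_permutation_test(X, Y, n_perm=1000, seed=0)
        assert res["rv_p"] == pytest.approx(1.0 / 1001.0, abs=1e-12)

    def test_determinism(self, rng):
        X = rng.normal(0, 1, (15, 4))
        Y = rng.normal(0, 1, (15, 4))
        a = pls_permutation_test(X, Y, n_perm=50, seed=9)
        b = pls_permutation_test(X, Y, n_perm=50, seed=9)
        assert a["rv_p"] == b["rv_p"]
        np.testing.assert_array_equal(a["axis_p"], b["axis_p"])

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 200
        for _ in range(reps):
            X = rng.normal(0, 1, (48, 5))
            Y = rng.normal(0, 1, (48, 5))
            p = pls_permutation_test(X, Y, n_perm=99,
                                     seed=int(rng.integers(2 ** 31)))["rv_p"]
            if p <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(500):
            X = rng.normal(0, 1, (20, 3))
            Y = rng.normal(0, 1, (20, 3))
            ps.append(pls_permutation_test(X, Y, n_perm=99,
                                           seed=int(rng.integers(2 ** 31)))["rv_p"])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestExtremeShapes:
    def test_multiple_zero_gives_means(self, rng):
        X = rng.normal(0, 1, (10, 4, 3))
        Y = rng.normal(0, 1, (10, 4, 3))
        res = two_block_pls(X, Y)
        m1 = X.mean(axis=0)
        m2 = Y.mean(axis=0)
        ext = pls_extreme_shapes(res, 0, 0.0, m1, m2)
        np.testing.assert_allclose(ext.plus[0], m1)
        np.testing.assert_allclose(ext.minus[1], m2)

    def test_symmetry_about_mean(self, rng):
        X = rng.normal(0, 1, (10, 4, 3))
        Y = rng.normal(0, 1, (10, 4, 3))
        res = two_block_pls(X, Y)
        m1, m2 = X.mean(axis=0), Y.mean(axis=0)
        ext = pls_extreme_shapes(res, 0, 1.5, m1, m2)
        np.testing.assert_allclose(ext.plus[0] + ext.minus[0], 2 * m1, atol=1e-10)
        np.testing.assert_allclose(ext.plus[1] + ext.minus[1], 2 * m2, atol=1e-10)

    def test_axis_out_of_range(self, rng):
        res = two_block_pls(rng.normal(size=(8, 4)), rng.normal(size=(8, 4)))
        with pytest.raises(PLSError):
            pls_extreme_shapes(res, 99, 1.0, np.zeros((2, 3)), np.zeros((2, 3)))

    def test_width_covariation_sign(self, rng):
        """PLS1 extremes reproduce the generator's coupled-width direction."""
        n, k = 60, 10
        width_mode1 = np.zeros((k, 3))
        width_mode1[:, 0] = np.linspace(-1, 1, k)  # x-widening
        width_mode2 = width_mode1 * 0.8
        base1 = rng.normal(0, 0.05, (k, 3))
        base2 = rng.normal(0, 0.05, (k, 3))
        lat = rng.normal(0, 1, n)
        X = base1 + lat[:, None, None] * width_mode1
        Y = base2 + lat[:, None, None] * width_mode2 + rng.normal(0, 0.02, (n, k, 3))
        res = two_block_pls(X, Y)
        ext = pls_extreme_shapes(res, 0, 1.0, X.mean(axis=0), Y.mean(axis=0))
        d1, d2 = ext.displacement
        # widths move together: displacement x-spreads have the same sign
        spread1 = d1[-1, 0] - d1[0, 0]
        spread2 = d2[-1, 0] - d2[0, 0]
        assert spread1 * spread2 > 0
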