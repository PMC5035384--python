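import numpy as np
import pytest

from morphsel import datasets
from morphsel.canonical import (
    CanonicalAnalysis,
    canonical_decompose,
    double_regression,
    eigen_permutation_test,
)
from morphsel.selection import quadratic_gradients, relative_fitness, standardize


class TestDecompose:
    def test_published_mating_matrix(self):
        gamma = datasets.mating_gamma()
        m, lam = canonical_decompose(gamma)
        np.testing.assert_allclose(lam, datasets.mating_eigenvalues(), atol=0.01)
        assert lam.sum() == pytest.approx(np.trace(gamma), abs=1e-10)
        assert np.trace(gamma) == pytest.approx(-0.844, abs=1e-10)

    def test_diagonal_gamma(self):
        gamma = np.diag([0.5, -0.3, 0.1])
        m, lam = canonical_decompose(gamma)
        np.testing.assert_allclose(lam, [0.5, 0.1, -0.3])
        # M is a (signed) permutation of the identity
        np.testing.assert_allclose(np.abs(m).sum(axis=1), 1.0)
        np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-12)

    def test_rotation_diagonalizes_and_conserves_trace(self, rng):
        a = rng.normal(size=(5, 5))
        gamma = (a + a.T) / 2
        m, lam = canonical_decompose(gamma)
        np.testing.assert_allclose(m @ gamma @ m.T, np.diag(lam), atol=1e-8)
        assert lam.sum() == pytest.approx(np.trace(gamma), abs=1e-8)
        assert np.all(np.diff(lam) <= 1e-12)  # descending

    def test_matches_characteristic_polynomial_oracle(self):
        gamma = np.array([[0.2, -0.1, 0.0], [-0.1, -0.4, 0.05], [0.0, 0.05, 0.1]])
        _, lam = canonical_decompose(gamma)
        oracle = np.sort(np.roots(np.poly(gamma)).real)[::-1]
        np.testing.assert_allclose(lam, oracle, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            canonical_decompose(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestDoubleRegression:
    def test_lambda_matches_eigenvalues_for_exact_quadratic_fitness(self, rng):
        n, p = 400, 3
        z = standardize(rng.normal(size=(n, p)))
        gamma_true = np.array(
            [[-0.4, 0.1, 0.0], [0.1, -0.2, 0.05], [0.0, 0.05, 0.3]]
        )
        w = 1.0 + 0.5 * np.einsum("ij,jk,ik->i", z, gamma_true, z)
        gamma_hat, _, _ = quadratic_gradients(z, w)
        m, lam = canonical_decompose(gamma_hat)
        _, lam_reg, _, _ = double_regression(z, w, m)
        np.testing.assert_allclose(np.sort(lam_reg), np.sort(lam), atol=1e-6)

    def test_null_theta_within_3_se(self, rng):
        n = 600
        z = standardize(rng.normal(size=(n, 4)))
        w = relative_fitness(rng.random(n))  # independent of traits
        gamma_hat, _, _ = quadratic_gradients(z, w)
        m, _ = canonical_decompose(gamma_hat)
        theta, _, theta_se, _ = double_regression(z, w, m)
        assert np.all(np.abs(theta) < 3 * theta_se)

    def test_deterministic_repeat(self, rng):
        z = standardize(rng.normal(size=(100, 3)))
        w = relative_fitness(rng.random(100))
        m, _ = canonical_decompose(quadratic_gradients(z, w)[0])
        out1 = double_regression(z, w, m)
        out2 = double_regression(z, w, m)
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a, b)


class TestEigenPermutation:
    def test_planted_stabilizing_axis_detected(self, rng):
        hits = 0
        reps = 20
        for r in range(reps):
            n = 500
            z = standardize(rng.normal(size=(n, 3)))
            w = relative_fitness(
                np.exp(-0.25 * z[:, 0] ** 2 + rng.normal(0, 0.1, n))
            )  # strong stabilizing axis (lambda ~ -0.5 on w scale)
            gamma_hat, _, _ = quadratic_gradients(z, w)
            m, lam = canonical_decompose(gamma_hat)
            p_lambda, _ = eigen_permutation_test(z, w, m, n_perm=499, seed=r)
            if p_lambda[np.argmin(lam)] <= 0.01:
                hits += 1
        assert hits >= 0.9 * reps

    def test_seed_determinism(self, rng):
        z = standardize(rng.normal(size=(80, 2)))
        w = relative_fitness(rng.random(80))
        m, _ = canonical_decompose(quadratic_gradients(z, w)[0])
        p1 = eigen_permutation_test(z, w, m, n_perm=199, seed=5)
        p2 = eigen_permutation_test(z, w, m, n_perm=199, seed=5)
        np.testing.assert_array_equal(p1[0], p2[0])


class TestCanonicalModel:
    def test_full_analysis_table(self, rng):
        n = 300
        z = standardize(rng.normal(size=(n, 3)))
        w = relative_fitness(1 + 0.1 * z[:, 0] + rng.normal(0, 0.2, n) ** 2)
        res = CanonicalAnalysis(z, w, trait_names=["pw", "cs", "rw1"]).fit(
            n_perm=199, seed=3
        )
        table = res.table()
        assert list(table.index) == ["m1", "m2", "m3"]
        np.testing.assert_allclose(res.m @ res.m.T, np.eye(3), atol=1e-8)
        assert "trace" in res.summary()
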