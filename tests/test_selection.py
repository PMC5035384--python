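import numpy as np
import pandas as pd
import pytest

from morphsel.selection import (
    SelectionGradientModel,
    linear_gradients,
    permutation_test,
    quadratic_gradients,
    relative_fitness,
    standardize,
)


class TestStandardize:
    def test_closed_form_sample_sd(self):
        z = standardize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])  # sample SD = 1

    def test_idempotent(self, rng):
        x = rng.normal(2.0, 3.0, size=(50, 4))
        once = standardize(x)
        twice = standardize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)
        np.testing.assert_allclose(once.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(once.std(axis=0, ddof=1), 1, atol=1e-8)

    def test_correlation_preserved(self, rng):
        x = rng.normal(size=(200, 3))
        x[:, 1] += 0.5 * x[:, 0]
        np.testing.assert_allclose(
            np.corrcoef(standardize(x).T), np.corrcoef(x.T), atol=1e-10
        )

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"pw": [1.0, 2.0], "cs": [3.0, 3.0]})
        with pytest.raises(ValueError, match="cs"):
            standardize(df)


class TestRelativeFitness:
    def test_study_design_counts(self):
        # 255 courted-only zeros and 245 maters
        raw = np.concatenate([np.zeros(255), np.ones(245)])
        w = relative_fitness(raw)
        assert w.mean() == pytest.approx(1.0)
        assert w[-1] == pytest.approx(500 / 245, abs=1e-10)
        assert w[0] == 0.0

    def test_constant_fitness_gives_unit(self):
        np.testing.assert_allclose(relative_fitness(np.full(10, 7.0)), 1.0)

    def test_per_episode_means(self):
        raw = np.array([0.0, 2.0, 10.0, 30.0])
        ep = np.array(["m", "m", "f", "f"])
        w = relative_fitness(raw, ep)
        assert w[:2].mean() == pytest.approx(1.0)
        assert w[2:].mean() == pytest.approx(1.0)

    def test_all_zero_episode_raises(self):
        with pytest.raises(ValueError, match="zero"):
            relative_fitness(np.zeros(5))


class TestGradients:
    def test_exact_linear_fit(self):
        z = standardize(np.linspace(-1, 1, 30))[:, None]
        w = 1.0 + 0.3 * z[:, 0]
        beta, _ = linear_gradients(z, w)
        assert beta[0] == pytest.approx(0.3, abs=1e-12)

    def test_pure_quadratic_doubles(self):
        z = standardize(np.linspace(-2, 2, 50))[:, None]
        w = z[:, 0] ** 2
        gamma, _, _ = quadratic_gradients(z, w)
        assert gamma[0, 0] == pytest.approx(2.0, abs=1e-10)

    def test_pure_correlational(self, rng):
        z = standardize(rng.normal(size=(200, 2)))
        w = z[:, 0] * z[:, 1]
        gamma, _, _ = quadratic_gradients(z, w)
        assert gamma[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert gamma[1, 0] == pytest.approx(1.0, abs=1e-10)
        assert abs(gamma[0, 0]) < 1e-10 and abs(gamma[1, 1]) < 1e-10

    def test_orthonormal_traits_beta_equals_covariance(self, rng):
        x = rng.normal(size=(300, 3))
        q, _ = np.linalg.qr(x - x.mean(axis=0))
        z = q * np.sqrt(300 - 1)  # orthogonal columns, unit sample variance
        w = 1 + 0.2 * z[:, 0] - 0.1 * z[:, 2] + rng.normal(0, 0.1, 300)
        beta, _ = linear_gradients(z, w)
        cov = (z * (w - w.mean())[:, None]).sum(axis=0) / (300 - 1)
        np.testing.assert_allclose(beta, cov, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        z = standardize(rng.normal(size=(40, 3)))
        w = relative_fitness(rng.poisson(5, size=40).astype(float))
        beta, _ = linear_gradients(z, w)
        x = np.column_stack([np.ones(40), z])
        oracle = np.linalg.solve(x.T @ x, x.T @ w)
        np.testing.assert_allclose(beta, oracle[1:], atol=1e-9)

    def test_planted_surface_recovery_large_n(self, rng):
        n = 5000
        beta_true = np.array([-0.1, 0.2, 0.0, 0.0, 0.05])
        z = standardize(rng.normal(size=(n, 5)))
        w = 1 + z @ beta_true + rng.normal(0, 0.5, n)
        beta, se = linear_gradients(z, w)
        assert np.all(np.abs(beta - beta_true) < 3 * se)

    def test_stabilizing_gamma_recovery(self, rng):
        n = 5000
        z = standardize(rng.normal(size=(n, 2)))
        w = 1 - 0.1 * (z**2).sum(axis=1) + rng.normal(0, 0.3, n)
        gamma, gamma_se, _ = quadratic_gradients(z, w)
        assert abs(gamma[0, 0] - (-0.2)) < 3 * gamma_se[0, 0]
        assert abs(gamma[1, 1] - (-0.2)) < 3 * gamma_se[1, 1]

    def test_rank_deficient_design_raises(self):
        z = np.column_stack([np.linspace(-1, 1, 20)] * 2)
        with pytest.raises(ValueError, match="rank"):
            linear_gradients(z, np.ones(20))

    def test_invariant_to_specimen_order(self, rng):
        z = standardize(rng.normal(size=(100, 3)))
        w = relative_fitness(rng.random(100))
        perm = rng.permutation(100)
        b1, _ = linear_gradients(z, w)
        b2, _ = linear_gradients(z[perm], w[perm])
        np.testing.assert_allclose(b1, b2, atol=1e-12)


class TestPermutationTest:
    def test_seed_determinism(self, rng):
        z = standardize(rng.normal(size=(80, 3)))
        w = relative_fitness(rng.random(80))
        p1 = permutation_test(z, w, "first", n_perm=199, seed=42)
        p2 = permutation_test(z, w, "first", n_perm=199, seed=42)
        np.testing.assert_array_equal(p1, p2)
        p3 = permutation_test(z, w, "first", n_perm=199, seed=43)
        assert not np.array_equal(p1, p3)

    def test_strong_effect_hits_permutation_floor(self, rng):
        n = 500
        z = standardize(rng.normal(size=(n, 1)))
        w = relative_fitness(np.exp(1.0 * z[:, 0]))  # beta ~ 1
        p = permutation_test(z, w, "first", n_perm=999, seed=1)
        assert p[0] <= 0.01  # at/near the 2/(N+1) floor

    def test_pvalues_in_unit_interval(self, rng):
        z = standardize(rng.normal(size=(60, 2)))
        w = relative_fitness(rng.random(60))
        p = permutation_test(z, w, "second", n_perm=99, seed=0)
        assert np.all(p > 0) and np.all(p <= 1)
        assert len(p) == 2 + 2 + 1  # linear, squared, cross terms


class TestModelObject:
    def test_fit_results_consistent(self, rng):
        n = 300
        traits = pd.DataFrame(
            standardize(rng.normal(size=(n, 3))), columns=["pw", "cs", "rw1"]
        )
        fitness = rng.integers(0, 2, n).astype(float)
        res = SelectionGradientModel(traits, fitness, episode="mating").fit(
            n_perm=199, seed=7
        )
        assert res.trait_names == ["pw", "cs", "rw1"]
        np.testing.assert_allclose(res.gamma, res.gamma.T)
        assert res.p_beta.shape == (3,)
        assert np.all((res.p_gamma > 0) & (res.p_gamma <= 1))
        assert "mating" in res.summary()
        table = res.gamma_table()
        assert list(table.columns) == ["beta", "pw", "cs", "rw1"]
        # beta (first-order) differs from the second-order linear terms
        assert res.beta.shape == res.linear2.shape
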