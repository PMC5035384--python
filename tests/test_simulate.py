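import numpy as np
import pytest

from morphsel.io import read_tps, write_tps
from morphsel.morphometry import GeneralizedProcrustes, relative_warps
from morphsel.simulate import (
    consensus_outline,
    default_truth,
    end_to_end_recovery,
    gen_fitness,
    gen_specimens,
    generate_study,
    implied_gradients,
    shape_axes,
)


class TestGenerator:
    def test_seed_determinism(self, outline_truth):
        a = gen_specimens(outline_truth, n=20, seed=9)
        b = gen_specimens(outline_truth, n=20, seed=9)
        np.testing.assert_array_equal(a.landmarks.coords, b.landmarks.coords)
        np.testing.assert_array_equal(
            a.traits["pw"].to_numpy(), b.traits["pw"].to_numpy()
        )
        c = gen_specimens(outline_truth, n=20, seed=10)
        assert not np.array_equal(a.landmarks.coords, c.landmarks.coords)

    def test_planted_axes_orthonormal_and_similarity_free(self):
        cons = consensus_outline(29)
        axes = shape_axes(cons, 3)
        np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-10)
        k = cons.shape[0]
        sims = [
            np.tile([1.0, 0.0], k),
            np.tile([0.0, 1.0], k),
            np.column_stack([-cons[:, 1], cons[:, 0]]).ravel(),
            cons.ravel(),
        ]
        for s in sims:
            np.testing.assert_allclose(axes @ s, 0, atol=1e-10)

    def test_noise_free_single_axis_recovered_by_rw1(self):
        truth = default_truth(
            n_axes=1, axis_sd=(0.03,), noise_sd=0.0, size_log_sd=0.0
        )
        data = gen_specimens(truth, n=60, seed=4)
        fit = GeneralizedProcrustes(data.landmarks).fit()
        scores = relative_warps(fit)
        assert scores.pct_variance[0] > 99.9

    def test_pw_cs_correlation(self):
        truth = default_truth()
        data = gen_specimens(truth, n=5000, seed=21)
        r = np.corrcoef(data.traits["pw"], np.log(data.traits["size"]))[0, 1]
        assert abs(r - truth.pw_cs_corr) < 0.04

    def test_two_digitizations_share_underlying_outline(self, outline_truth):
        data = gen_specimens(outline_truth, n=15, seed=2, digitizations=2)
        a, b = data.landmarks.coords, data.landmarks_repeat.coords
        assert not np.array_equal(a, b)
        # same true outline: differences are pure digitizing noise
        assert np.abs(a - b).max() < 10 * outline_truth.noise_sd

    def test_roundtrip_through_tps(self, tmp_path, outline_specimens):
        path = tmp_path / "spec.tps"
        write_tps(outline_specimens.landmarks, str(path))
        back = read_tps(str(path))
        np.testing.assert_allclose(
            back.coords, outline_specimens.landmarks.coords, atol=1e-12
        )


class TestFitness:
    def test_binary_rate_matches_target(self):
        truth = default_truth()
        data = gen_specimens(truth, n=10000, seed=1)
        fit = gen_fitness(data.z_true, truth, seed=2)
        assert abs(fit.mean() - truth.mating_rate) < 0.015

    def test_zero_fraction_and_range(self):
        truth = default_truth(fitness_model="zero-inflated-count")
        data = gen_specimens(truth, n=10000, seed=3)
        fit = gen_fitness(data.z_true, truth, seed=4)
        assert abs((fit == 0).mean() - truth.zero_fraction) < 0.02
        positive = fit[fit > 0]
        assert positive.min() >= truth.count_range[0]
        assert positive.max() <= truth.count_range[1]

    def test_null_surface_gives_independent_fitness(self, rng):
        truth = default_truth(beta=np.zeros(5), gamma=np.zeros((5, 5)))
        data = gen_specimens(truth, n=2000, seed=5)
        fit = gen_fitness(data.z_true, truth, seed=6)
        corr = [abs(np.corrcoef(data.z_true[:, j], fit)[0, 1]) for j in range(5)]
        assert max(corr) < 3.5 / np.sqrt(2000)

    def test_unattainable_rate_raises(self):
        truth = default_truth(mating_rate=0.999999999)
        data = gen_specimens(truth, n=50, seed=7)
        with pytest.raises(ValueError, match="unattainable"):
            # degenerate: logistic cannot reach ~1 while eta spans the surface
            gen_fitness(data.z_true, default_truth(mating_rate=1.0 - 1e-15),
                        seed=8)


class TestImpliedGradients:
    def test_logistic_link_attenuates_gamma(self):
        truth = default_truth()
        beta_imp, gamma_imp = implied_gradients(truth)
        # stabilizing structure preserved, magnitude attenuated by the link
        assert np.all(np.diag(gamma_imp) < 0)
        assert np.all(np.abs(np.diag(gamma_imp)) < np.abs(np.diag(truth.gamma)))

    def test_null_surface_implies_null_gradients(self):
        truth = default_truth(beta=np.zeros(5), gamma=np.zeros((5, 5)))
        beta_imp, gamma_imp = implied_gradients(truth, n_mc=100_000)
        assert np.abs(beta_imp).max() < 0.01
        assert np.abs(gamma_imp).max() < 0.01


class TestStudyAndRecovery:
    def test_generate_study_design(self):
        mating, fert = generate_study(seed=17)
        assert mating.n == 500 and fert.n == 508
        assert set(mating.traits["episode"]) == {"mating"}
        assert set(fert.traits["episode"]) == {"fertilization"}
        assert set(np.unique(mating.fitness)) <= {0.0, 1.0}
        assert fert.fitness.max() > 1

    def test_recovery_determinism(self):
        a = end_to_end_recovery(n=400, seed=8)
        b = end_to_end_recovery(n=400, seed=8)
        np.testing.assert_array_equal(a.beta_hat, b.beta_hat)
        np.testing.assert_array_equal(a.gamma_hat, b.gamma_hat)

    def test_rmse_improves_with_n(self):
        """Average gamma error shrinks from n=500 to n=5000 over seeds."""
        def rmse(n, seeds):
            errs = []
            for s in seeds:
                rep = end_to_end_recovery(n=n, seed=s)
                errs.append(
                    np.sqrt(((rep.gamma_hat - rep.gamma_true) ** 2).mean())
                )
            return np.mean(errs)

        seeds = range(5)
        assert rmse(5000, seeds) < rmse(500, seeds)

    def test_linear_only_truth_gives_null_gamma(self):
        truth = default_truth(
            beta=np.array([0.1, -0.15, 0.2, 0.0, 0.05]), gamma=np.zeros((5, 5))
        )
        rep = end_to_end_recovery(truth, n=5000, seed=19)
        assert np.abs(rep.gamma_z).max() < 3.0
        assert np.abs(rep.beta_z).max() < 3.0
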