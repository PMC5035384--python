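import numpy as np
import pytest

from morphsel.io import SliderTable
from morphsel.morphometry import (
    GeneralizedProcrustes,
    bending_energy,
    centroid_size,
    relative_warps,
    shape_at_score,
    tps_deformation_grid,
)
from morphsel.simulate import consensus_outline, gen_specimens, shape_axes


def _similarity(config, theta, scale, shift):
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return config @ rot.T * scale + np.asarray(shift)


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert centroid_size(square) == pytest.approx(np.sqrt(2.0))

    def test_homogeneity_and_translation_invariance(self, rng):
        config = rng.normal(size=(7, 2))
        cs = centroid_size(config)
        assert centroid_size(3.5 * config) == pytest.approx(3.5 * cs)
        assert centroid_size(config + np.array([10.0, -3.0])) == pytest.approx(cs)

    def test_rotation_invariance(self, rng):
        config = rng.normal(size=(5, 2))
        rotated = _similarity(config, 1.1, 1.0, (0, 0))
        assert centroid_size(rotated) == pytest.approx(centroid_size(config))

    def test_degenerate_configuration_raises(self):
        with pytest.raises(ValueError, match="coincident"):
            centroid_size(np.ones((4, 2)))


class TestGeneralizedProcrustes:
    def test_copies_of_one_shape_align_exactly(self, rng):
        base = rng.normal(size=(6, 2))
        configs = np.array(
            [
                _similarity(base, rng.uniform(0, 2 * np.pi), rng.uniform(0.2, 3.0),
                            rng.normal(size=2))
                for _ in range(5)
            ]
        )
        fit = GeneralizedProcrustes(configs).fit()
        dev = ((fit.aligned - fit.consensus) ** 2).sum()
        assert dev < 1e-10

    def test_mean_deviation_is_zero(self, outline_specimens):
        fit = GeneralizedProcrustes(outline_specimens.landmarks).fit()
        np.testing.assert_allclose(
            fit.aligned.mean(axis=0), fit.consensus, atol=1e-7
        )
        # consensus centred at origin with unit centroid size
        np.testing.assert_allclose(fit.consensus.mean(axis=0), 0, atol=1e-12)
        assert centroid_size(fit.consensus) == pytest.approx(1.0)
        assert np.all(fit.centroid_sizes > 0)

    def test_invariant_to_input_similarity_transform(self, outline_specimens, rng):
        coords = outline_specimens.landmarks.coords.copy()
        fit1 = GeneralizedProcrustes(coords).fit()
        coords2 = coords.copy()
        coords2[3] = _similarity(coords2[3], 0.9, 2.7, (4.0, -2.0))
        fit2 = GeneralizedProcrustes(coords2).fit()
        np.testing.assert_allclose(fit1.aligned, fit2.aligned, atol=1e-8)

    def test_matches_pairwise_oracle_on_three_specimens(self, triangle_set):
        """With identical shapes, GPA must agree with direct pairwise
        ordinary Procrustes superimposition of each onto the mean."""
        fit = GeneralizedProcrustes(triangle_set).fit()
        # oracle: align each (centred, unit-CS) copy onto the consensus
        # by the closed-form 2-D rotation, independently of the GPA loop
        for i in range(3):
            x = triangle_set.coords[i] - triangle_set.coords[i].mean(axis=0)
            x /= centroid_size(x)
            y = fit.consensus
            # closed-form optimal 2-D rotation angle
            num = (x[:, 0] * y[:, 1] - x[:, 1] * y[:, 0]).sum()
            den = (x * y).sum()
            theta = np.arctan2(num, den)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            np.testing.assert_allclose(x @ rot.T, fit.aligned[i], atol=1e-9)

    def test_sliding_never_increases_bending_energy(self, outline_truth):
        from morphsel.simulate import _outline_sliders

        data = gen_specimens(outline_truth, n=12, seed=5)
        sliders = _outline_sliders(outline_truth)
        plain = GeneralizedProcrustes(data.landmarks).fit()
        be_before = sum(
            bending_energy(plain.consensus, plain.aligned[i])
            for i in range(plain.n_specimens)
        )
        slid = GeneralizedProcrustes(data.landmarks, sliders).fit()
        be_after = sum(
            bending_energy(slid.consensus, slid.aligned[i])
            for i in range(slid.n_specimens)
        )
        assert slid.slid
        assert be_after <= be_before + 1e-10


class TestRelativeWarps:
    def test_planted_axis_recovered(self, outline_truth):
        truth = outline_truth
        from dataclasses import replace

        single = replace(truth, n_axes=1, axis_sd=(0.03,), noise_sd=0.0,
                         size_log_sd=0.0)
        data = gen_specimens(single, n=50, seed=2)
        fit = GeneralizedProcrustes(data.landmarks).fit()
        scores = relative_warps(fit)
        assert scores.pct_variance[0] > 99.0
        cos = abs(scores.loadings[0] @ data.axes[0])
        assert cos > 0.99

    def test_dimension_bound_and_bookkeeping(self, outline_truth):
        data = gen_specimens(outline_truth, n=80, seed=3)
        fit = GeneralizedProcrustes(data.landmarks).fit()
        scores = relative_warps(fit)
        k = data.landmarks.k
        assert scores.n_nondegenerate() <= 2 * k - 4
        assert np.all(np.diff(scores.pct_variance) <= 1e-12)
        assert scores.pct_variance.sum() == pytest.approx(100.0)
        np.testing.assert_allclose(scores.scores.mean(axis=0), 0, atol=1e-10)
        # eigenvalue sum equals total Procrustes (tangent-space) variance;
        # build the similarity basis independently of the implementation
        flat = fit.aligned.reshape(80, -1)
        centered = flat - flat.mean(axis=0)
        k_lm = data.landmarks.k
        tx = np.tile([1.0, 0.0], k_lm)
        ty = np.tile([0.0, 1.0], k_lm)
        rot = np.column_stack([-fit.consensus[:, 1], fit.consensus[:, 0]]).ravel()
        scl = fit.consensus.ravel()
        q, _ = np.linalg.qr(np.array([tx, ty, rot, scl]).T)
        tangent = centered - (centered @ q) @ q.T
        total = tangent.var(axis=0, ddof=1).sum()
        assert scores.eigenvalues.sum() == pytest.approx(total)
        # and the projection removes only a negligible share of variance
        assert total > 0.999 * centered.var(axis=0, ddof=1).sum()

    def test_too_few_specimens_raises(self, consensus29):
        fit = GeneralizedProcrustes(np.array([consensus29, consensus29 * 1.0])).fit()
        with pytest.raises(ValueError, match="at least 3"):
            relative_warps(fit)


class TestShapeAtScore:
    @pytest.fixture
    def scores(self, outline_specimens):
        fit = GeneralizedProcrustes(outline_specimens.landmarks).fit()
        return relative_warps(fit)

    def test_zero_score_is_consensus(self, scores):
        np.testing.assert_allclose(
            shape_at_score(scores, 0, 0.0), scores.consensus, atol=1e-12
        )

    def test_symmetry_about_consensus(self, scores):
        plus = shape_at_score(scores, 1, 0.05)
        minus = shape_at_score(scores, 1, -0.05)
        np.testing.assert_allclose(
            (plus + minus) / 2, scores.consensus, atol=1e-12
        )

    def test_projection_roundtrip(self, scores):
        config = shape_at_score(scores, 0, 0.037)
        recovered = (config - scores.consensus).ravel() @ scores.loadings[0]
        assert recovered == pytest.approx(0.037, abs=1e-8)

    def test_out_of_range_component(self, scores):
        with pytest.raises(IndexError):
            shape_at_score(scores, scores.n_components + 3, 0.0)


class TestDeformationGrid:
    def test_identity_when_target_is_consensus(self, consensus29):
        gx, gy = tps_deformation_grid(consensus29, consensus29, grid_size=10)
        # undeformed grid: rows/cols of a rectangular lattice
        ref_x, ref_y = np.meshgrid(
            np.linspace(gx.min(), gx.max(), 10), np.linspace(gy.min(), gy.max(), 10)
        )
        assert np.abs(gx - ref_x).max() < 1e-10
        assert np.abs(gy - ref_y).max() < 1e-10

    def test_affine_target_has_zero_bending_energy(self, consensus29):
        affine = consensus29 @ np.array([[1.2, 0.3], [-0.1, 0.9]]) + [0.5, -0.2]
        assert bending_energy(consensus29, affine) == pytest.approx(0.0, abs=1e-8)

    def test_interpolation_property(self, consensus29, rng):
        target = consensus29 + rng.normal(0, 0.02, size=consensus29.shape)
        from morphsel.morphometry import _tps_system, _tps_evaluate

        full = _tps_system(consensus29)
        rhs = np.zeros((consensus29.shape[0] + 3, 2))
        rhs[: consensus29.shape[0]] = target
        coefs = np.linalg.solve(full, rhs)
        warped = _tps_evaluate(consensus29, coefs, consensus29)
        np.testing.assert_allclose(warped, target, atol=1e-9)

    def test_coincident_landmarks_raise(self):
        bad = np.zeros((4, 2))
        bad[1] = [1, 0]
        bad[2] = [1, 0]
        bad[3] = [0, 1]
        with pytest.raises(ValueError):
            tps_deformation_grid(bad, bad + 0.1)
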