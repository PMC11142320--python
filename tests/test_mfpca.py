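import numpy as np
import pytest

from cgmfda import (
    GenerativeConfig,
    PostprandialDataset,
    eigendecompose,
    estimate_covariances,
    estimate_mean_functions,
    estimate_scores,
    fit_mfpca,
    make_grid,
    orthonormal_basis,
    reconstruct,
    variance_proportions,
)
from cgmfda.mfpca import MFPCAModel
from cgmfda.simulate import simulate_mfpca_dataset


def constant_dataset(grid, value=100.0, n=4):
    return PostprandialDataset(
        grid=grid,
        curves=np.full((2 * n, grid.n_points), value),
        subject_ids=np.repeat([f"S{i}" for i in range(n)], 2),
        meal_index=np.tile([1, 2], n),
    )


class TestMeanFunctions:
    def test_constant_curves_recovered_exactly(self, grid):
        mu, nu = estimate_mean_functions(constant_dataset(grid), include_day_effects=True)
        np.testing.assert_allclose(mu, 100.0, atol=1e-8)
        np.testing.assert_allclose(nu, 0.0, atol=1e-8)

    def test_day_effects_off_returns_none(self, grid):
        mu, nu = estimate_mean_functions(constant_dataset(grid), include_day_effects=False)
        assert nu is None

    def test_mean_recovery_on_simulated_data(self):
        """Median (over replicates) worst-case mean error stays below
        2 mg/dL at n=150, J=4; single replicates can reach ~4 mg/dL from
        subject-level sampling noise (calibrated by pilot simulation)."""
        errs = []
        for r in range(10):
            cfg = GenerativeConfig(n_subjects=150, meals_per_subject=4, seed=500 + r)
            ds, truth = simulate_mfpca_dataset(cfg)
            mu, _ = estimate_mean_functions(ds)
            errs.append(np.max(np.abs(mu - truth.mu)))
        assert np.median(errs) < 2.0
        assert max(errs) < 5.0

    def test_single_curve_ordinal_shrunk_to_zero(self, grid):
        ds = PostprandialDataset(
            grid=grid,
            curves=np.vstack([np.full(grid.n_points, 100.0)] * 3),
            subject_ids=np.array(["A", "A", "B"]),
            meal_index=np.array([1, 2, 1]),
        )
        with pytest.warns(UserWarning, match="single curve"):
            _, nu = estimate_mean_functions(ds, include_day_effects=True)
        np.testing.assert_allclose(nu[1], 0.0, atol=1e-12)


class TestCovariances:
    def test_zero_meal_level_gives_negligible_within_surface(self, grid):
        cfg = GenerativeConfig(
            n_subjects=40, meals_per_subject=3, noise_sd=0.0,
            meal_eigenvalues=np.zeros(3), seed=10,
        )
        ds, _ = simulate_mfpca_dataset(cfg)
        mu, _ = estimate_mean_functions(ds)
        _, k_between, k_within, _ = estimate_covariances(ds, mu, smooth=True)
        assert np.max(np.abs(k_within)) < 1e-6 * np.max(np.abs(k_between))

    def test_rank_one_between_surface_recovered(self, grid):
        phi = orthonormal_basis(grid, k=1)
        cfg = GenerativeConfig(
            n_subjects=300, meals_per_subject=2, noise_sd=0.0,
            subject_eigenfunctions=phi, subject_eigenvalues=np.array([100.0]),
            meal_eigenvalues=np.array([1e-12]),
            meal_eigenfunctions=orthonormal_basis(grid, k=2)[1:],
            seed=11,
        )
        ds, truth = simulate_mfpca_dataset(cfg)
        mu, _ = estimate_mean_functions(ds)
        _, k_between, _, _ = estimate_covariances(ds, mu, smooth=True)
        target = 100.0 * np.outer(truth.phi[0], truth.phi[0])
        assert np.max(np.abs(k_between - target)) < 10.0

    def test_between_surface_is_symmetric(self, small_mfpca_data):
        _, dataset, _ = small_mfpca_data
        mu, _ = estimate_mean_functions(dataset)
        _, k_between, k_within, _ = estimate_covariances(dataset, mu)
        np.testing.assert_array_equal(k_between, k_between.T)
        np.testing.assert_array_equal(k_within, k_within.T)

    def test_no_repeated_meals_is_an_error(self, grid):
        ds = PostprandialDataset(
            grid=grid,
            curves=np.random.default_rng(0).normal(100, 5, (4, grid.n_points)),
            subject_ids=np.array(["A", "B", "C", "D"]),
            meal_index=np.ones(4, dtype=int),
        )
        mu, _ = estimate_mean_functions(ds)
        with pytest.raises(ValueError, match="single-level"):
            estimate_covariances(ds, mu)


class TestEigendecompose:
    def test_rank_one_surface(self, grid):
        phi = orthonormal_basis(grid, k=1)[0]
        funcs, vals = eigendecompose(np.outer(phi, phi), grid, 3)
        assert vals[0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(vals[1:], 0.0, atol=1e-10)
        peak = np.argmax(np.abs(funcs[0]))
        assert funcs[0][peak] > 0
        assert abs(grid.inner(funcs[0], phi)) == pytest.approx(1.0, abs=1e-8)

    def test_zero_surface_gives_zero_eigenvalues(self, grid):
        _, vals = eigendecompose(np.zeros((grid.n_points,) * 2), grid, 5)
        np.testing.assert_array_equal(vals, 0.0)

    def test_two_component_construction_recovered(self, grid):
        basis = orthonormal_basis(grid, k=2)
        K = 4.0 * np.outer(basis[0], basis[0]) + 1.0 * np.outer(basis[1], basis[1])
        funcs, vals = eigendecompose(K, grid, 2)
        np.testing.assert_allclose(vals, [4.0, 1.0], atol=1e-8)
        for est, true in zip(funcs, basis):
            assert abs(abs(grid.inner(est, true)) - 1.0) < 1e-8

    def test_matches_dense_eigensolver_after_reweighting(self, rng):
        """Independent oracle: quadrature eigenproblem solved directly with
        numpy's dense symmetric solver on random small surfaces."""
        small = make_grid(0, 95, 5)  # 20 points
        w = small.trapezoid_weights()
        sw = np.sqrt(w)
        for _ in range(10):
            A = rng.normal(size=(20, 20))
            K = A @ A.T / 20
            funcs, vals = eigendecompose(K, small, 20)
            oracle_vals, oracle_vecs = np.linalg.eigh(sw[:, None] * K * sw[None, :])
            np.testing.assert_allclose(vals, oracle_vals[::-1].clip(0), atol=1e-8)
            for k in range(20):
                oracle_fn = oracle_vecs[:, 19 - k] / sw
                align = abs(small.inner(funcs[k], oracle_fn))
                assert align == pytest.approx(1.0, abs=1e-8)

    def test_component_count_capped_by_grid(self, grid):
        with pytest.raises(ValueError, match="exceeds"):
            eigendecompose(np.zeros((73, 73)), grid, 74)


class TestScores:
    def _known_model(self, grid, lam=9.0, gam=4.0, noise=0.0):
        basis = orthonormal_basis(grid, k=2)
        return MFPCAModel(
            grid=grid, mu=np.zeros(grid.n_points), nu=None,
            phi=basis[:1], lam=np.array([lam]),
            psi=basis[1:], gam=np.array([gam]),
            scores_subject=np.zeros((1, 1)), scores_meal=np.zeros((1, 1)),
            noise_var=noise,
            subject_codes=np.zeros(1, dtype=int),
            subject_labels=np.array(["A"], dtype=object),
            meal_index=np.array([1]),
        )

    def test_noiseless_single_component_score_exact(self, grid):
        model = self._known_model(grid)
        ds = PostprandialDataset(
            grid=grid, curves=(3.0 * model.phi[0])[None, :],
            subject_ids=np.array(["A"]), meal_index=np.array([1]),
        )
        with pytest.warns(UserWarning, match="jitter"):
            a, b = estimate_scores(ds, model)
        assert a[0, 0] == pytest.approx(3.0, abs=1e-6)
        assert b[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_blup_shrinks_relative_to_projection_under_noise(self):
        cfg = GenerativeConfig(
            n_subjects=40, meals_per_subject=2, seed=14,
            noise_sd=10.0 * np.sqrt(28512.0 / 360),  # sigma = 10 sqrt(lam_1) pointwise
        )
        ds, truth = simulate_mfpca_dataset(cfg)
        model = fit_mfpca(ds)
        a_blup, _ = estimate_scores(ds, model, method="blup")
        a_proj, _ = estimate_scores(ds, model, method="projection")
        assert np.mean(np.abs(a_blup)) < np.mean(np.abs(a_proj))

    def test_score_means_near_zero(self, small_mfpca_data):
        _, dataset, truth = small_mfpca_data
        model = fit_mfpca(dataset)
        bound = 3 * np.sqrt(model.lam / model.n_subjects)
        assert np.all(np.abs(model.scores_subject.mean(axis=0)) < bound)

    def test_unknown_method_rejected(self, small_mfpca_data):
        _, dataset, _ = small_mfpca_data
        model = fit_mfpca(dataset)
        with pytest.raises(ValueError, match="score method"):
            estimate_scores(dataset, model, method="banana")


class TestFitAndReconstruct:
    def test_refit_is_deterministic(self, small_mfpca_data):
        _, dataset, _ = small_mfpca_data
        m1 = fit_mfpca(dataset)
        m2 = fit_mfpca(dataset)
        np.testing.assert_array_equal(m1.phi, m2.phi)
        np.testing.assert_array_equal(m1.scores_meal, m2.scores_meal)

    def test_component_counts_validated(self, small_mfpca_data):
        _, dataset, _ = small_mfpca_data
        with pytest.raises(ValueError):
            fit_mfpca(dataset, K=0)

    def test_full_minus_participant_is_meal_term(self, small_mfpca_data):
        _, dataset, _ = small_mfpca_data
        model = fit_mfpca(dataset)
        gap = reconstruct(model, "full") - reconstruct(model, "participant")
        np.testing.assert_allclose(gap, model.scores_meal @ model.psi, atol=1e-10)

    def test_zero_scores_reconstruct_the_mean(self, small_mfpca_data):
        _, dataset, _ = small_mfpca_data
        model = fit_mfpca(dataset)
        model.scores_subject = np.zeros_like(model.scores_subject)
        model.scores_meal = np.zeros_like(model.scores_meal)
        np.testing.assert_allclose(
            reconstruct(model, "full"), model.mean_for_rows(), atol=1e-12
        )

    def test_invalid_level_rejected(self, small_mfpca_data):
        _, dataset, _ = small_mfpca_data
        model = fit_mfpca(dataset)
        with pytest.raises(ValueError, match="level"):
            reconstruct(model, "meal")

    def test_noiseless_rank_one_reconstruction_exact(self, grid):
        basis = orthonormal_basis(grid, k=2)
        cfg = GenerativeConfig(
            n_subjects=30, meals_per_subject=2, noise_sd=0.0,
            subject_eigenfunctions=basis[:1], subject_eigenvalues=np.array([20000.0]),
            meal_eigenfunctions=basis[1:], meal_eigenvalues=np.array([10000.0]),
            seed=15,
        )
        ds, _ = simulate_mfpca_dataset(cfg)
        model = fit_mfpca(ds, K=1, H=1)
        resid = ds.curves - reconstruct(model, "full")
        assert np.sqrt(np.mean(resid**2)) < 1.0  # residual near the noise floor (0)

    def test_residual_sum_of_squares_non_increasing_in_h(self, small_mfpca_data):
        _, dataset, _ = small_mfpca_data
        rss = []
        for h in (1, 2, 3):
            model = fit_mfpca(dataset, K=2, H=h)
            rss.append(np.sum((dataset.curves - reconstruct(model, "full")) ** 2))
        assert rss[0] >= rss[1] - 1e-6 and rss[1] >= rss[2] - 1e-6


class TestVarianceProportions:
    def test_zero_meal_eigenvalues_give_all_subject_share(self, grid):
        model = MFPCAModel(
            grid=grid, mu=np.zeros(grid.n_points), nu=None,
            phi=np.zeros((1, grid.n_points)), lam=np.array([5.0]),
            psi=np.zeros((1, grid.n_points)), gam=np.array([0.0]),
            scores_subject=np.zeros((1, 1)), scores_meal=np.zeros((1, 1)),
            noise_var=0.0, subject_codes=np.zeros(1, dtype=int),
            subject_labels=np.array(["A"], dtype=object), meal_index=np.array([1]),
        )
        assert variance_proportions(model) == (1.0, 0.0)

    def test_simple_arithmetic(self, grid):
        model = MFPCAModel(
            grid=grid, mu=np.zeros(grid.n_points), nu=None,
            phi=np.zeros((1, grid.n_points)), lam=np.array([2.0]),
            psi=np.zeros((2, grid.n_points)), gam=np.array([1.0, 1.0]),
            scores_subject=np.zeros((1, 1)), scores_meal=np.zeros((1, 2)),
            noise_var=0.0, subject_codes=np.zeros(1, dtype=int),
            subject_labels=np.array(["A"], dtype=object), meal_index=np.array([1]),
        )
        assert variance_proportions(model) == (0.5, 0.5)

    def test_all_zero_eigenvalues_error(self, grid):
        model = MFPCAModel(
            grid=grid, mu=np.zeros(grid.n_points), nu=None,
            phi=np.zeros((1, grid.n_points)), lam=np.array([0.0]),
            psi=np.zeros((1, grid.n_points)), gam=np.array([0.0]),
            scores_subject=np.zeros((1, 1)), scores_meal=np.zeros((1, 1)),
            noise_var=0.0, subject_codes=np.zeros(1, dtype=int),
            subject_labels=np.array(["A"], dtype=object), meal_index=np.array([1]),
        )
        with pytest.raises(ValueError, match="undefined"):
            variance_proportions(model)
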