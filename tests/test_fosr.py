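import numpy as np
import pandas as pd
import pytest

from cgmfda import (
    CovariateTable,
    FoSROptions,
    GenerativeConfig,
    PostprandialDataset,
    fit_fosr,
    fit_fosr_pointwise,
    joint_confidence_bands,
    predict,
)
from cgmfda.fosr import estimate_random_effect_functions, smooth_coefficients
from cgmfda.lmm import fit_random_intercept
from cgmfda.simulate import simulate_fosr_dataset
from cgmfda.smoothing import PSpline1D


def intercept_table(subject_ids, meal_index, extra=None):
    frame = pd.DataFrame(
        {"subject_id": subject_ids, "meal_index": meal_index, "group": "all",
         "intercept": 1.0}
    )
    cols = ["intercept"]
    if extra is not None:
        for name, vals in extra.items():
            frame[name] = vals
            cols.append(name)
    return CovariateTable(frame=frame, design_columns=cols)


class TestPointwiseFit:
    def test_single_subject_rejected(self, grid):
        ds = PostprandialDataset(
            grid=grid, curves=np.zeros((2, grid.n_points)),
            subject_ids=np.array(["A", "A"]), meal_index=np.array([1, 2]),
        )
        cov = intercept_table(ds.subject_ids, ds.meal_index)
        with pytest.raises(ValueError, match="single subject"):
            fit_fosr_pointwise(ds, cov)

    def test_constant_response_fits_exactly_with_zero_variances(self, grid):
        ds = PostprandialDataset(
            grid=grid, curves=np.full((6, grid.n_points), 42.0),
            subject_ids=np.repeat(["A", "B", "C"], 2),
            meal_index=np.tile([1, 2], 3),
        )
        cov = intercept_table(ds.subject_ids, ds.meal_index)
        with pytest.warns(UserWarning, match="collapsed"):
            raw = fit_fosr_pointwise(ds, cov)
        np.testing.assert_allclose(raw.beta[:, 0], 42.0, atol=1e-8)
        np.testing.assert_allclose(raw.sigma2_u, 0.0, atol=1e-10)
        np.testing.assert_allclose(raw.sigma2_e, 0.0, atol=1e-10)

    def test_reduces_to_ols_when_random_effect_absent(self, grid):
        """With alpha = 0 and white noise the variance component collapses
        and the mixed-model estimate must agree with plain least squares."""
        cfg = GenerativeConfig(
            n_subjects=40, meals_per_subject=3, random_effect_sd=0.0, seed=31
        )
        ds, cov, _ = simulate_fosr_dataset(cfg)
        raw = fit_fosr_pointwise(ds, cov)
        X = cov.design_matrix()
        ols = np.linalg.lstsq(X, ds.curves, rcond=None)[0].T  # (m, L)
        collapsed = raw.collapsed
        assert collapsed.mean() > 0.5  # most grid points collapse
        np.testing.assert_allclose(
            raw.beta[collapsed], ols[collapsed], atol=1e-6
        )

    def test_matches_statsmodels_mixedlm_at_single_point(self, small_fosr_data):
        sm_api = pytest.importorskip("statsmodels.api")
        _, ds, cov, _ = small_fosr_data
        raw = fit_fosr_pointwise(ds, cov)
        codes, _ = ds.subject_codes()
        t = 24  # two hours post meal
        md = sm_api.MixedLM(ds.curves[:, t], cov.design_matrix(), groups=codes)
        fit = md.fit(reml=True)
        np.testing.assert_allclose(raw.beta[t], np.asarray(fit.params)[:10], rtol=1e-4)
        np.testing.assert_allclose(raw.beta_se[t], np.asarray(fit.bse)[:10], rtol=1e-3)
        assert raw.sigma2_e[t] == pytest.approx(fit.scale, rel=1e-3)


class TestSmoothing:
    def test_straight_line_unchanged(self, grid):
        sm = PSpline1D(grid.points, n_basis=35)
        line = 2.0 + 0.05 * grid.points
        fitted, _ = sm.fit(line)
        np.testing.assert_allclose(fitted, line, atol=1e-6)

    def test_white_noise_range_shrinks(self, grid, rng):
        sm = PSpline1D(grid.points)
        noise = rng.normal(0, 1, grid.n_points)
        fitted, _ = sm.fit(noise)
        assert np.ptp(fitted) < np.ptp(noise)

    def test_smoothing_none_passes_raw_through(self, small_fosr_data):
        _, ds, cov, _ = small_fosr_data
        raw = fit_fosr_pointwise(ds, cov)
        beta, beta_se, _ = smooth_coefficients(
            raw, ds.grid, cov.design_columns, smoothing="none"
        )
        np.testing.assert_array_equal(beta, raw.beta.T)
        np.testing.assert_array_equal(beta_se, raw.beta_se.T)


class TestRandomEffectFunctions:
    def test_centered_to_zero_mean(self, small_fosr_data):
        _, ds, cov, _ = small_fosr_data
        raw = fit_fosr_pointwise(ds, cov)
        alpha = estimate_random_effect_functions(raw, ds.grid)
        np.testing.assert_allclose(alpha.mean(axis=0), 0.0, atol=1e-6)

    def test_null_generative_alpha_estimated_small(self):
        cfg = GenerativeConfig(
            n_subjects=60, meals_per_subject=4, random_effect_sd=0.0, seed=33
        )
        ds, cov, _ = simulate_fosr_dataset(cfg)
        model = fit_fosr(ds, cov, options=FoSROptions(compute_bands=False))
        # pointwise alpha sd is at most ~sigma_e/sqrt(J); use 3x that scale
        bound = 3.0 * np.sqrt(np.maximum(model.sigma2_eps, 1e-12) / 4).max()
        assert np.max(np.abs(model.alpha)) < max(bound, 1.0)

    def test_alpha_recovery_correlates_with_truth(self):
        cfg = GenerativeConfig(n_subjects=100, meals_per_subject=6, seed=34)
        ds, cov, truth = simulate_fosr_dataset(cfg)
        model = fit_fosr(ds, cov, options=FoSROptions(compute_bands=False))
        cors = [
            np.corrcoef(model.alpha[i], truth.alpha[i])[0, 1]
            for i in range(100)
        ]
        assert np.mean(cors) > 0.7


class TestBandsAndPrediction:
    def test_joint_multiplier_at_least_pointwise_z(self, small_fosr_data):
        _, ds, cov, _ = small_fosr_data
        model = fit_fosr(ds, cov, options=FoSROptions(compute_bands=False))
        bands = joint_confidence_bands(model, level=0.95, B=120, seed=3)
        for info in bands.values():
            assert info["multiplier"] >= 1.959
            assert np.all(info["joint_lower"] <= info["pointwise_lower"] + 1e-12)
            assert np.all(info["joint_upper"] >= info["pointwise_upper"] - 1e-12)

    def test_bands_deterministic_under_seed(self, small_fosr_data):
        _, ds, cov, _ = small_fosr_data
        model = fit_fosr(ds, cov, options=FoSROptions(compute_bands=False))
        b1 = joint_confidence_bands(model, B=120, seed=9)
        b2 = joint_confidence_bands(model, B=120, seed=9)
        for name in b1:
            np.testing.assert_array_equal(b1[name]["joint_lower"], b2[name]["joint_lower"])

    def test_small_b_warns(self, small_fosr_data):
        _, ds, cov, _ = small_fosr_data
        model = fit_fosr(ds, cov, options=FoSROptions(compute_bands=False))
        with pytest.warns(UserWarning, match="unstable"):
            joint_confidence_bands(model, B=50, seed=1)

    def test_conditional_minus_marginal_is_alpha(self, small_fosr_data):
        _, ds, cov, _ = small_fosr_data
        model = fit_fosr(ds, cov, options=FoSROptions(compute_bands=False))
        gap = predict(model, cov, "conditional") - predict(model, cov, "marginal")
        codes = np.array([model.subject_code(s) for s in cov.frame["subject_id"]])
        np.testing.assert_allclose(gap, model.alpha[codes], atol=1e-10)

    def test_predictions_linear_in_covariates(self, small_fosr_data, rng):
        _, ds, cov, _ = small_fosr_data
        model = fit_fosr(ds, cov, options=FoSROptions(compute_bands=False))
        f1 = cov.frame.copy()
        f2 = cov.frame.copy()
        for col in ("carbohydrates", "fats", "age"):
            f1[col] = rng.normal(50, 10, len(f1))
            f2[col] = rng.normal(50, 10, len(f2))
        fsum = f1.copy()
        for col in model.coef_names:
            fsum[col] = f1[col] + f2[col]
        t1 = CovariateTable(frame=f1, design_columns=cov.design_columns)
        t2 = CovariateTable(frame=f2, design_columns=cov.design_columns)
        ts = CovariateTable(frame=fsum, design_columns=cov.design_columns)
        np.testing.assert_allclose(
            predict(model, ts, "marginal"),
            predict(model, t1, "marginal") + predict(model, t2, "marginal"),
            atol=1e-8,
        )

    def test_conditional_for_unseen_subject_rejected(self, small_fosr_data):
        _, ds, cov, _ = small_fosr_data
        model = fit_fosr(ds, cov, options=FoSROptions(compute_bands=False))
        frame = cov.frame.copy()
        frame.loc[0, "subject_id"] = "GHOST"
        bad = CovariateTable(frame=frame, design_columns=cov.design_columns)
        with pytest.raises(ValueError, match="marginal"):
            predict(model, bad, "conditional")


class TestStratifiedFit:
    def test_empty_stratum_rejected(self, small_fosr_data):
        _, ds, cov, _ = small_fosr_data
        with pytest.raises(ValueError, match="no rows"):
            fit_fosr(ds, cov, stratum="unknown-group")

    def test_stratified_fit_differs_from_pooled(self, small_fosr_data):
        _, ds, cov, _ = small_fosr_data
        pooled = fit_fosr(ds, cov, options=FoSROptions(compute_bands=False))
        normo = fit_fosr(
            ds, cov, stratum="normoglycemic", options=FoSROptions(compute_bands=False)
        )
        assert normo.stratum == "normoglycemic"
        assert normo.subject_labels.size < pooled.subject_labels.size
        assert not np.allclose(pooled.beta, normo.beta)

    def test_group_specific_carbohydrate_effect_recovered(self):
        """Two strata with different carbohydrate coefficient functions are
        each recovered by their own stratified fit."""
        rows = []
        rng = np.random.default_rng(55)

        def sampler(r, labels, counts):
            out = []
            for i, (lab, c) in enumerate(zip(labels, counts)):
                grp = "normoglycemic" if i % 2 == 0 else "prediabetes"
                for j in range(c):
                    out.append(
                        {"subject_id": lab, "meal_index": j + 1, "group": grp,
                         "intercept": 1.0,
                         "carbohydrates": float(r.normal(60, 40))}
                    )
            return pd.DataFrame(out)

        cfg = GenerativeConfig(
            n_subjects=120, meals_per_subject=4, seed=56,
            random_effect_sd=5.0,
            covariate_sampler=sampler,
            beta_functions={
                "intercept": lambda t: 100.0 + 0.0 * t,
                "carbohydrates": lambda t: 0.2 * np.exp(-(((t - 70) / 80) ** 2)),
            },
        )
        ds, cov, truth = simulate_fosr_dataset(cfg)
        # amplify the carbohydrate effect in the prediabetes stratum by 2x
        pre = (cov.frame["group"] == "prediabetes").to_numpy()
        extra = cov.frame.loc[pre, "carbohydrates"].to_numpy()[:, None] * truth.beta[
            "carbohydrates"
        ]
        ds.curves[pre] += extra
        w = ds.grid.trapezoid_weights()
        for grp, scale in (("normoglycemic", 1.0), ("prediabetes", 2.0)):
            model = fit_fosr(ds, cov, stratum=grp, options=FoSROptions(compute_bands=False))
            l = model.coef_names.index("carbohydrates")
            ise = np.sum(w * (model.beta[l] - scale * truth.beta["carbohydrates"]) ** 2)
            assert ise < 0.01

    def test_refit_serializes_identically(self, small_fosr_data, tmp_path):
        from cgmfda.io import write_fosr_model

        _, ds, cov, _ = small_fosr_data
        opts = FoSROptions(band_B=120, seed=5)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_fosr_model(fit_fosr(ds, cov, options=opts), p1)
        write_fosr_model(fit_fosr(ds, cov, options=opts), p2)
        assert p1.read_bytes() == p2.read_bytes()
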