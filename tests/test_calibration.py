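"""Linear adjustment, robust nonlinear fitting, AIC selection, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from lakeloads import models, synth
from lakeloads.calibration import (
    FitResult, aic_of_fit, apply_detection_limit, fit_all_hypotheses,
    fit_linear_adjustment, goodness_of_fit, improvement_summary,
    residual_hrt_bias_test, robust_fit, select_best,
)

from conftest import calibration_frame


class TestDetectionLimit:
    def test_below_limit_substituted(self):
        vals, flags = apply_detection_limit([0.003, 0.004, 0.01])
        np.testing.assert_allclose(vals, [0.002, 0.004, 0.01])
        assert list(flags) == [True, False, False]

    def test_series_above_limit_unchanged(self):
        tn = np.array([0.2, 0.5, 1.1])
        vals, flags = apply_detection_limit(tn, detection_limit=0.01)
        np.testing.assert_array_equal(vals, tn)
        assert not flags.any()

    def test_nonpositive_substitute_rejected(self):
        with pytest.raises(ValueError):
            apply_detection_limit([0.003], substitute=0.0)


class TestLinearAdjustment:
    def test_identity_fit(self):
        obs = np.array([0.1, 0.5, 1.0, 2.0])
        intercept, slope, fit = fit_linear_adjustment(obs, obs)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert slope == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_ratio_moves_intercept_only(self):
        pred = np.array([0.1, 0.5, 1.0, 2.0])
        intercept, slope, _ = fit_linear_adjustment(0.5 * pred, pred)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(np.log10(0.5))

    def test_slope_recovered_within_sampling_error(self):
        rng = np.random.default_rng(8)
        pred = 10 ** rng.normal(-0.3, 0.4, 131)
        obs = 10 ** (0.1 + 0.8 * np.log10(pred) + rng.normal(0, 0.26, 131))
        _, slope, fit = fit_linear_adjustment(obs, pred)
        se = 0.26 / (np.std(np.log10(pred)) * np.sqrt(131))
        assert abs(slope - 0.8) < 2 * se
        assert fit.n_obs == 131

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_linear_adjustment([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(np.linalg.LinAlgError):
            fit_linear_adjustment([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        obs = np.array([0.1, 0.5, 2.0])
        rmse, adj_r2 = goodness_of_fit(obs, obs)
        assert rmse == pytest.approx(0.0, abs=1e-12)
        assert adj_r2 == pytest.approx(1.0)

    def test_known_residuals(self):
        obs = np.array([1.0, 2.0, 1.0, 2.0])
        pred = obs * np.array([1.122018, 0.891251, 1.122018, 0.891251])
        rmse, _ = goodness_of_fit(obs, pred)  # residuals are +-0.05 log10
        assert rmse == pytest.approx(0.05, abs=1e-4)

    def test_scale_equivariance_and_relabel_invariance(self):
        rng = np.random.default_rng(3)
        obs = 10 ** rng.normal(0, 0.3, 30)
        pred = obs * 10 ** rng.normal(0, 0.1, 30)
        rmse1, r1 = goodness_of_fit(obs, pred)
        rmse2, r2 = goodness_of_fit(7.0 * obs, 7.0 * pred)
        perm = rng.permutation(30)
        rmse3, r3 = goodness_of_fit(obs[perm], pred[perm])
        assert rmse2 == pytest.approx(rmse1) and r2 == pytest.approx(r1)
        assert rmse3 == pytest.approx(rmse1) and r3 == pytest.approx(r1)


class TestAic:
    def test_closed_form(self):
        aic = aic_of_fit([0.1, -0.1, 0.1, -0.1], 1)
        assert aic == pytest.approx(4 * np.log(0.01) + 4, abs=1e-2)

    def test_penalty_term(self):
        r = [0.1, -0.1, 0.1, -0.1]
        assert aic_of_fit(r, 2) == pytest.approx(aic_of_fit(r, 1) + 2)

    def test_zero_rss_sentinel(self):
        assert aic_of_fit([0.0, 0.0, 0.0], 1) == float("-inf")


class TestRobustFit:
    def zero_noise_data(self):
        rng = np.random.default_rng(12)
        conc_in = 10 ** rng.normal(-0.1, 0.3, 80)
        tau = 10 ** rng.normal(-0.8, 0.6, 80)
        z = 10 ** rng.normal(0.4, 0.3, 80)
        return conc_in, tau, z

    def test_interpolating_fit_recovers_truth(self):
        conc_in, tau, z = self.zero_noise_data()
        truth = models.get_model("H4").with_coefficients(a=1.3, b=0.47)
        obs = models.predict_concentration(truth, conc_in, tau, z)
        fit = robust_fit(models.get_model("H4"), obs, conc_in, tau, z)
        assert fit.converged
        assert fit.coefficients["a"] == pytest.approx(1.3, abs=1e-6)
        assert fit.coefficients["b"] == pytest.approx(0.47, abs=1e-6)

    def test_coefficient_recovery_under_noise(self):
        cfg = synth.SimulationConfig(n_lakes=500, seed=100, sigma_obs_N=0.1)
        ds = synth.end_to_end_fixture(cfg)
        data = calibration_frame(ds, "N")
        fit = robust_fit(models.get_model("H6"), data["obs"], data["conc_in"],
                         data["tau_yr"], data["z_mean_m"])
        for name, truth in zip("abcd", (2.0, 0.38, 0.29, 1.14)):
            assert abs(fit.coefficients[name] - truth) / truth < 0.15

    def test_outlier_downweighted(self):
        cfg = synth.SimulationConfig(n_lakes=200, seed=21, sigma_obs_N=0.1)
        ds = synth.end_to_end_fixture(cfg)
        d = calibration_frame(ds, "N")
        spec = models.get_model("H6")
        clean = robust_fit(spec, d["obs"], d["conc_in"], d["tau_yr"], d["z_mean_m"])
        obs = d["obs"].copy()
        obs.iloc[5] *= 100.0
        contaminated = robust_fit(spec, obs, d["conc_in"], d["tau_yr"], d["z_mean_m"])
        plain = robust_fit(spec, obs, d["conc_in"], d["tau_yr"], d["z_mean_m"],
                           tuning=1e9)  # huge tuning constant = plain NLS
        assert contaminated.robust_weights[5] < 0.2
        rel = {k: abs(contaminated.coefficients[k] - clean.coefficients[k])
               / clean.coefficients[k] for k in "abcd"}
        rel_plain = {k: abs(plain.coefficients[k] - clean.coefficients[k])
                     / clean.coefficients[k] for k in "abcd"}
        assert max(rel.values()) < 0.02
        assert max(rel_plain.values()) > 0.02

    def test_huge_tuning_equals_plain_nls_oracle(self):
        import scipy.optimize

        conc_in, tau, z = self.zero_noise_data()
        rng = np.random.default_rng(4)
        obs = 10 ** (np.log10(models.predict_concentration(
            models.get_model("H4"), conc_in, tau, z)) + rng.normal(0, 0.15, 80))
        fit = robust_fit(models.get_model("H4"), obs, conc_in, tau, z, tuning=1e9)

        def resid(theta):
            a, b = np.exp(theta)
            return np.log10(obs) - np.log10(conc_in / (1 + a * tau ** b))

        sol = scipy.optimize.least_squares(resid, np.log([1.12, 0.53]), method="lm")
        a, b = np.exp(sol.x)
        assert fit.coefficients["a"] == pytest.approx(a, rel=1e-6)
        assert fit.coefficients["b"] == pytest.approx(b, rel=1e-6)

    def test_deterministic(self):
        cfg = synth.SimulationConfig(n_lakes=100, seed=5)
        ds = synth.end_to_end_fixture(cfg)
        d = calibration_frame(ds, "N")
        fits = [robust_fit(models.get_model("H6"), d["obs"], d["conc_in"],
                           d["tau_yr"], d["z_mean_m"]) for _ in range(2)]
        assert fits[0].coefficients == fits[1].coefficients


class TestSelection:
    def fake_fit(self, hid, aic, n_free=1, converged=True):
        return FitResult(hypothesis_id=hid, nutrient="N", coefficients={},
                         free=tuple("x" * n_free), residuals=np.zeros(3),
                         predictions=np.ones(3), rmse=0.1, adj_r2=0.5,
                         aic=aic, n_obs=3, converged=converged)

    def test_lowest_aic_wins(self):
        fits = {"H6": self.fake_fit("H6", -69.9), "H4": self.fake_fit("H4", -8.4),
                "H0": self.fake_fit("H0", 24.7)}
        assert select_best(fits) == "H6"

    def test_tie_breaks_to_fewer_coefficients(self):
        fits = {"Hx": self.fake_fit("Hx", 1.0, n_free=4),
                "Hy": self.fake_fit("Hy", 1.0, n_free=2)}
        assert select_best(fits) == "Hy"

    def test_order_invariance_and_single_converged(self):
        fits = {"H1": self.fake_fit("H1", 3.0), "H2": self.fake_fit("H2", 2.0)}
        assert select_best(fits) == select_best(dict(reversed(fits.items())))
        lone = {"H1": self.fake_fit("H1", 3.0),
                "H2": self.fake_fit("H2", 2.0, converged=False)}
        assert select_best(lone) == "H1"
        with pytest.raises(ValueError):
            select_best({"H2": self.fake_fit("H2", 2.0, converged=False)})


class TestHrtBias:
    def test_identical_groups(self):
        resid = np.array([0.1, -0.2, 0.05, 0.1, -0.2, 0.05])
        tau = np.array([0.01, 0.01, 0.01, 1.0, 1.0, 1.0])
        rep = residual_hrt_bias_test(resid, tau)
        assert rep.t == pytest.approx(0.0, abs=1e-12)
        assert rep.p == pytest.approx(1.0)

    def test_hand_vectors_welch_df(self):
        resid = np.array([1.0, 2, 3, 1, 2, 3])
        tau = np.array([0.01, 0.01, 0.01, 1.0, 1.0, 1.0])
        rep = residual_hrt_bias_test(resid, tau)
        assert rep.df == pytest.approx(4.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(9)
        short = rng.normal(0.17, 0.21, 33)
        long_ = rng.normal(-0.17, 0.19, 33)
        resid = np.concatenate([short, long_])
        tau = np.concatenate([np.full(33, 0.01), np.full(33, 1.0)])
        rep = residual_hrt_bias_test(resid, tau)
        assert 4 < abs(rep.t) < 10
        assert rep.p < 0.001
        assert (rep.n_short, rep.n_long) == (33, 33)

    def test_empty_group_skipped(self):
        rep = residual_hrt_bias_test([0.1, 0.2], [1.0, 2.0])
        assert rep.skipped and np.isnan(rep.t)


class TestImprovement:
    def fit_with_r2(self, r2, ids=("a", "b", "c")):
        return FitResult(hypothesis_id="H", nutrient="N", coefficients={},
                         free=(), residuals=np.zeros(3), predictions=np.ones(3),
                         rmse=0.1, adj_r2=r2, aic=0.0, n_obs=3, converged=True,
                         lake_ids=np.asarray(ids))

    @pytest.mark.parametrize("r2_lin,r2_vw,expect", [
        (0.431, 0.618, 18.7),
        (0.351, 0.541, 19.0),
        (0.5, 0.5, 0.0),
    ])
    def test_percentage_point_gain(self, r2_lin, r2_vw, expect):
        got = improvement_summary(self.fit_with_r2(r2_lin), self.fit_with_r2(r2_vw))
        assert got == pytest.approx(expect, abs=0.05)

    def test_mismatched_lakes_rejected(self):
        with pytest.raises(ValueError):
            improvement_summary(self.fit_with_r2(0.4),
                                self.fit_with_r2(0.6, ids=("a", "b", "z")))
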