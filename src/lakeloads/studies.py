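"""Replication studies on synthetic lake populations.

Each function generates data under the default study conditions, runs the
relevant pipeline stages, and returns the summary numbers: coefficient
recovery for the calibrated retention model, AIC model selection frequency,
the residence-time bias contrast between the linear and retention-model
adjustments, and a full headline run (fits, improvement, retention,
below-1:1 fractions, band coverage).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assessment, calibration, models, network, synth

EQ1_TRUTH = {"a": 2.0, "b": 0.38, "c": 0.29, "d": 1.14}
EQ2_TRUTH = {"a": 89.0, "b": 0.40, "c": 0.57, "d": 1.08}


def _calibration_data(dataset, nutrient):
    t = dataset.truth.merge(dataset.observed, on="lake_id")
    data = pd.DataFrame({
        "lake_id": t["lake_id"],
        "obs": t["obs_TN" if nutrient == "N" else "obs_TP"],
        "conc_in": t[f"conc_in_{nutrient}"],
        "conc_out": 1000.0 * t[f"export_{nutrient}"] / t["flow_m3yr"],
        "tau_yr": t["tau_yr"],
        "z_mean_m": t["z_mean_m"],
    })
    if nutrient == "P":
        data["obs"], _ = calibration.apply_detection_limit(data["obs"])
    return data


def recovery_study(base_seed: int = 0, n_seeds: int = 20, n_lakes: int = 500,
                   sigma_obs: float = 0.1) -> dict:
    """Refit the retention model to data generated from its own calibrated
    nitrogen coefficients; report the median relative error per coefficient
    across seeded replicates."""
    errors = {k: [] for k in EQ1_TRUTH}
    for i in range(n_seeds):
        cfg = synth.SimulationConfig(n_lakes=n_lakes, seed=base_seed + i,
                                     sigma_obs_N=sigma_obs)
        ds = synth.end_to_end_fixture(cfg)
        data = _calibration_data(ds, "N")
        fit = calibration.robust_fit(models.get_model("H6"), data["obs"],
                                     data["conc_in"], data["tau_yr"],
                                     data["z_mean_m"])
        for k, truth in EQ1_TRUTH.items():
            errors[k].append(abs(fit.coefficients[k] - truth) / truth)
    return {k: float(np.median(v)) for k, v in errors.items()}


def selection_study(base_seed: int = 0, n_seeds: int = 20,
                    n_lakes: int = 500) -> dict:
    """Fit all nine hypotheses per nutrient across seeded replicates and
    count how often the depth-and-input-dependent retention model (H6, the
    generating family) attains the lowest AIC."""
    wins = {"N": 0, "P": 0}
    for i in range(n_seeds):
        ds = synth.end_to_end_fixture(
            synth.SimulationConfig(n_lakes=n_lakes, seed=base_seed + i))
        for nutrient in ("N", "P"):
            data = _calibration_data(ds, nutrient)
            fits = calibration.fit_all_hypotheses(data, nutrient)
            if calibration.select_best(fits) == "H6":
                wins[nutrient] += 1
    return {"n_seeds": n_seeds, **wins}


def bias_study(seed: int = 0, n_lakes: int = 500) -> dict:
    """Residence-time bias contrast: the linear adjustment's residuals differ
    between short and long residence-time lakes, the retention model's do
    not.  Returns the Welch reports keyed by (hypothesis, nutrient)."""
    ds = synth.end_to_end_fixture(synth.SimulationConfig(n_lakes=n_lakes, seed=seed))
    out = {}
    for nutrient in ("N", "P"):
        data = _calibration_data(ds, nutrient)
        tau = data["tau_yr"].to_numpy()
        for hid in ("H0", "H6"):
            fit = calibration.fit_hypothesis(hid, data, nutrient)
            out[(hid, nutrient)] = calibration.residual_hrt_bias_test(
                fit.residuals, tau)
    return out


def headline_run(seed: int = 0, n_lakes: int = 500) -> dict:
    """One full analysis under the default study conditions.

    Aggregates reach loads through the flow network, applies the nitrogen
    mass-balance filter, calibrates all nine hypotheses per nutrient,
    selects by AIC, extrapolates the selected models, and summarizes.
    """
    ds = synth.end_to_end_fixture(synth.SimulationConfig(n_lakes=n_lakes, seed=seed))
    budgets = network.aggregate_all_lakes(ds.reach_table, ds.flow_table)
    retained = network.mass_balance_filter(budgets)
    lakes = network.attach_morphometry(retained, ds.morphometry)

    observed = ds.observed.rename(columns={})
    results: dict = {
        "n_lakes": n_lakes,
        "n_mass_balance_retained": int(len(retained)),
    }
    for nutrient in ("N", "P"):
        data = calibration.build_calibration_table(observed, lakes, nutrient)
        fits = calibration.fit_all_hypotheses(data, nutrient)
        best = calibration.select_best(fits)
        fit_lin, fit_best = fits["H0"], fits[best]
        tau = data["tau_yr"].to_numpy()
        results[nutrient] = {
            "n_calibration": int(len(data)),
            "best": best,
            "fits": fits,
            "adj_r2_linear": fit_lin.adj_r2,
            "adj_r2_best": fit_best.adj_r2,
            "rmse_linear": fit_lin.rmse,
            "rmse_best": fit_best.rmse,
            "improvement_pctpts": calibration.improvement_summary(fit_lin, fit_best),
            "pct_below_one_to_one": 100.0 * float(
                np.mean(data["obs"] < data["conc_out"])),
            "bias_linear": calibration.residual_hrt_bias_test(fit_lin.residuals, tau),
            "bias_best": calibration.residual_hrt_bias_test(fit_best.residuals, tau),
        }
        spec = models.get_model(best).with_coefficients(
            **{k: v for k, v in fit_best.coefficients.items()
               if k in models.COEF_NAMES})
        preds, _, summary = models.predict_population(spec, lakes, nutrient)
        results[nutrient]["retention"] = summary
        results[nutrient]["coefficients"] = fit_best.coefficients

        prob = observed[observed["is_probability_sample"]]
        merged = preds.merge(prob[["lake_id", "design_weight"]], on="lake_id")
        col = "obs_TN" if nutrient == "N" else "obs_TP"
        if len(merged) >= 2:
            ref = assessment.weighted_cdf(prob[col].to_numpy(),
                                          prob["design_weight"].to_numpy())
            test = assessment.weighted_cdf(merged["conc_pred"].to_numpy(),
                                           merged["design_weight"].to_numpy())
            results[nutrient]["cdf_band_coverage"] = assessment.cdf_within_band(
                test, ref)
    return results
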