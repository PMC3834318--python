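"""Stage orchestration: simulate → aggregate → calibrate → predict → assess.

Each stage reads/writes CSV under the configured output directory and
appends its filter counts to a run manifest, so the lake bookkeeping
(generated → budgeted → mass-balance retained → calibrated → extrapolated)
is auditable from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assessment, calibration, io, models, network, synth

logger = logging.getLogger(__name__)


def _outdir(config) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _update_manifest(config, updates: dict) -> dict:
    path = _outdir(config) / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "counts": {},
    }
    manifest["counts"].update(updates.pop("counts", {}))
    manifest.update(updates)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def stage_simulate(config) -> synth.SyntheticDataset:
    """Generate a synthetic dataset and write the four input tables."""
    sim = synth.SimulationConfig(n_lakes=config.n_lakes, seed=config.seed)
    ds = synth.end_to_end_fixture(sim)
    out = _outdir(config)
    io.write_table(ds.flow_table, out / "flow_table.csv", "flow_table")
    io.write_table(ds.reach_table, out / "reach_table.csv", "reach_table")
    io.write_table(ds.morphometry, out / "morphometry.csv", "morphometry")
    obs = ds.observed.rename(columns={})
    io.write_table(obs, out / "observed.csv", "observed")
    # generating truth: written for scoring, never read back by the pipeline
    ds.truth.to_csv(out / "truth.csv", index=False)
    _update_manifest(config, {"seed": config.seed,
                              "counts": {"lakes_generated": int(config.n_lakes),
                                         "reaches_generated": int(len(ds.reach_table))}})
    return ds


def _load_inputs(config):
    out = _outdir(config)
    flow = io.read_flow_table(config.flow_table or out / "flow_table.csv")
    reach = io.read_reach_table(config.reach_table or out / "reach_table.csv")
    morpho = io.read_morphometry(config.morphometry or out / "morphometry.csv")
    observed = io.read_observed(config.observed or out / "observed.csv")
    return flow, reach, morpho, observed


def stage_aggregate(config) -> pd.DataFrame:
    """Aggregate reach loads to lake budgets, filter on the N mass balance,
    attach morphometry, and write budgets plus rejects."""
    flow, reach, morpho, _ = _load_inputs(config)
    budgets = network.aggregate_all_lakes(reach, flow, config.cfs_to_m3yr)
    retained = network.mass_balance_filter(budgets, config.mass_balance_rel_tol)
    lakes = network.attach_morphometry(retained, morpho)
    out = _outdir(config)
    io.write_budgets(lakes, out / "budgets.csv")
    rejects = budgets.loc[~budgets["lake_id"].isin(retained["lake_id"])]
    zero_flow = lakes.loc[~(lakes["flow_m3yr"] > 0)]
    pd.concat([rejects, zero_flow]).to_csv(out / "budget_rejects.csv", index=False)
    _update_manifest(config, {"counts": {
        "lakes_budgeted": int(len(budgets)),
        "lakes_mass_balance_retained": int(len(retained)),
        "lakes_zero_flow": int(len(zero_flow)),
    }})
    return lakes


def stage_calibrate(config, lakes: pd.DataFrame | None = None):
    """Fit the requested hypotheses per nutrient and select the best by AIC.

    Writes the model-selection report (hypothesis x nutrient x rmse/adjR²/
    aic), the selected coefficients, and the residence-time bias tests for
    the linear and selected models.
    """
    out = _outdir(config)
    if lakes is None:
        lakes = pd.read_csv(out / "budgets.csv", comment="#")
    _, _, _, observed = _load_inputs(config)

    fits_by_nutrient, best, coef_rows, bias_rows = {}, {}, [], []
    for nutrient in ("N", "P"):
        data = calibration.build_calibration_table(observed, lakes, nutrient)
        fits = calibration.fit_all_hypotheses(
            data, nutrient, hypotheses=config.hypotheses,
            tuning=config.huber_tuning, max_iter=config.max_iter)
        fits_by_nutrient[nutrient] = fits
        best[nutrient] = calibration.select_best(fits)
        for hid, f in fits.items():
            for name, value in f.coefficients.items():
                coef_rows.append({"nutrient": nutrient, "hypothesis": hid,
                                  "coefficient": name, "value": value,
                                  "free": name in f.free})
        tau = data["tau_yr"].to_numpy()
        for hid in {"H0", best[nutrient]}:
            rep = calibration.residual_hrt_bias_test(
                fits[hid].residuals, tau, config.hrt_short_max, config.hrt_long_min)
            bias_rows.append({"nutrient": nutrient, "hypothesis": hid, **vars(rep)})

    report = calibration.fit_report(fits_by_nutrient)
    report.to_csv(out / "fit_report.csv", index=False)
    pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
    pd.DataFrame(bias_rows).to_csv(out / "hrt_bias.csv", index=False)
    _update_manifest(config, {
        "selected": best,
        "counts": {"hypotheses_fit": int(len(report)),
                   "lakes_calibrated_N": int(report.loc[report.nutrient == "N", "n_obs"].max()),
                   "lakes_calibrated_P": int(report.loc[report.nutrient == "P", "n_obs"].max())},
    })
    return fits_by_nutrient, best


def stage_predict(config, lakes: pd.DataFrame | None = None,
                  fits_by_nutrient: dict | None = None, best: dict | None = None):
    """Extrapolate the selected calibrated models to the lake population."""
    out = _outdir(config)
    if lakes is None:
        lakes = pd.read_csv(out / "budgets.csv", comment="#")
    if fits_by_nutrient is None or best is None:
        fits_by_nutrient, best = stage_calibrate(config, lakes)

    predictions = {}
    for nutrient in ("N", "P"):
        fit = fits_by_nutrient[nutrient][best[nutrient]]
        spec = models.get_model(fit.hypothesis_id).with_coefficients(
            **{k: v for k, v in fit.coefficients.items() if k in models.COEF_NAMES})
        preds, rejects, summary = models.predict_population(spec, lakes, nutrient)
        preds.to_csv(out / f"predictions_{nutrient}.csv", index=False)
        rejects.to_csv(out / f"prediction_rejects_{nutrient}.csv", index=False)
        _update_manifest(config, {"counts": {
            f"lakes_predicted_{nutrient}": summary["n"],
            f"lakes_prediction_rejected_{nutrient}": summary["n_rejected"]}})
        predictions[nutrient] = preds
    return predictions


def stage_classify(config, predictions: dict | None = None) -> pd.DataFrame:
    """Trophic-state classification of the predicted concentrations."""
    out = _outdir(config)
    if predictions is None:
        predictions = {n: pd.read_csv(out / f"predictions_{n}.csv") for n in ("N", "P")}
    thresholds = {
        "N": assessment.TrophicThresholds("N", *config.trophic_tn),
        "P": assessment.TrophicThresholds("P", *config.trophic_tp),
    }
    merged = predictions["N"][["lake_id", "conc_pred"]].rename(
        columns={"conc_pred": "conc_TN"}).merge(
        predictions["P"][["lake_id", "conc_pred"]].rename(
            columns={"conc_pred": "conc_TP"}), on="lake_id")
    merged["TN_class"] = assessment.trophic_state(merged["conc_TN"], thresholds["N"])
    merged["TP_class"] = assessment.trophic_state(merged["conc_TP"], thresholds["P"])
    merged[["lake_id", "TN_class", "TP_class"]].to_csv(
        out / "trophic_classes.csv", index=False)
    _update_manifest(config, {"counts": {"lakes_classified": int(len(merged))}})
    return merged


def stage_cdf(config, predictions: dict | None = None) -> dict:
    """Design-weighted CDFs of observed vs predicted concentrations.

    Observed curves use the probability-sample lakes and their design
    weights; predicted curves are compared against the observed 95% band
    on the observed support.
    """
    out = _outdir(config)
    _, _, _, observed = _load_inputs(config)
    if predictions is None:
        predictions = {n: pd.read_csv(out / f"predictions_{n}.csv") for n in ("N", "P")}
    coverage = {}
    for nutrient, col in (("N", "obs_TN"), ("P", "obs_TP")):
        prob = observed[observed["is_probability_sample"]]
        ref = assessment.weighted_cdf(prob[col].to_numpy(),
                                      prob["design_weight"].to_numpy())
        pd.DataFrame({"support": ref.support, "cdf": ref.cdf,
                      "lo95": ref.lo95, "hi95": ref.hi95}).to_csv(
            out / f"cdf_observed_{nutrient}.csv", index=False)
        preds = predictions[nutrient].merge(prob[["lake_id", "design_weight"]],
                                            on="lake_id")
        if len(preds) >= 2:
            test = assessment.weighted_cdf(preds["conc_pred"].to_numpy(),
                                           preds["design_weight"].to_numpy())
            coverage[nutrient] = assessment.cdf_within_band(test, ref)
    _update_manifest(config, {"cdf_band_coverage": coverage})
    return coverage


def run_pipeline(config, command: str = "all"):
    """Run one named stage or the whole chain.

    Commands: simulate, aggregate, calibrate, predict, classify, cdf, all.
    """
    stages = {
        "simulate": stage_simulate,
        "aggregate": stage_aggregate,
        "calibrate": stage_calibrate,
        "predict": stage_predict,
        "classify": stage_classify,
        "cdf": stage_cdf,
    }
    if command == "all":
        stage_simulate(config)
        lakes = stage_aggregate(config)
        fits, best = stage_calibrate(config, lakes)
        predictions = stage_predict(config, lakes, fits, best)
        stage_classify(config, predictions)
        stage_cdf(config, predictions)
        return json.loads((_outdir(config) / "manifest.json").read_text())
    if command not in stages:
        raise ValueError(f"unknown command: {command!r}")
    return stages[command](config)
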