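"""Synthetic reach networks, loads, morphometry and observed concentrations.

The generator emulates the statistical structure the pipeline assumes:

* each lake is a short chain of internal reaches fed by 0–3 headwater
  tributaries, with per-reach incremental nutrient loads drawn lognormally
  (kg/yr) and flow proportional to accumulated drainage units;
* total loads accumulate downstream conserving nitrogen mass (optional
  first-order in-lake decay for phosphorus, mirroring a regional load model
  that retains phosphorus but not nitrogen in lakes);
* lake surface area and maximum depth are lognormal, volume is the cone
  approximation area * zmax / 3;
* observed summer concentrations are the truth model's prediction with
  additive Gaussian noise on the log10 scale;
* survey design weights are inverse inclusion probabilities by area
  stratum, with a fraction of lakes marked as hand-selected reference
  sites;
* a configurable fraction of lakes gets a planted diversion (scaled-down
  outflow loads) violating the nitrogen mass balance.

Identical seeds give identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import network
from .models import PRESETS, InputOutputModelSpec, predict_concentration

TP_DETECTION_LIMIT = 0.004


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a population of small northeastern-style lakes: median
    inflow TN around 0.8 mg/L and TP around 0.03 mg/L, residence times
    spanning well past the short (<0.04 yr) and long (>0.4 yr) survey
    quartiles, and observation noise matching the residual scatter of a
    calibrated retention model (0.21 log10 units for TN, 0.36 for TP).
    """

    n_lakes: int = 500
    seed: int = 0
    internal_reaches: tuple = (1, 4)        # inclusive range per lake
    input_reaches: tuple = (0, 3)
    tributary_units: tuple = (1, 5)         # drainage units per tributary
    mu_log_inc_N: float = math.log(250.0)   # per-unit incremental N, kg/yr
    sigma_log_inc_N: float = 1.0
    mu_log_inc_P: float = math.log(10.0)    # per-unit incremental P, kg/yr
    sigma_log_inc_P: float = 1.0
    runoff_cfs_per_unit: float = 0.6
    p_decay_per_reach: float = 0.1          # first-order in-lake P loss
    mu_log_area: float = math.log(3.0e5)    # m2 (median 30 ha)
    sigma_log_area: float = 1.2
    mu_log_zmax: float = math.log(5.0)      # m, floored at 1 m
    sigma_log_zmax: float = 1.0
    truth_N: InputOutputModelSpec = PRESETS["Eq1"]
    truth_P: InputOutputModelSpec = PRESETS["Eq2"]
    sigma_obs_N: float = 0.21               # log10 noise sd
    sigma_obs_P: float = 0.36
    area_strata_m2: tuple = (1.0e5, 5.0e5)  # stratum bounds
    inclusion_probs: tuple = (0.15, 0.3, 0.6)
    diversion_fraction: float = 0.0125      # lakes violating the N balance
    diversion_loss: float = 0.3             # fraction of outflow load removed

    def __post_init__(self):
        if self.n_lakes < 0:
            raise ValueError("n_lakes must be nonnegative")
        for name in ("mu_log_inc_N", "mu_log_inc_P"):
            pass
        for name in ("sigma_log_inc_N", "sigma_log_inc_P", "runoff_cfs_per_unit",
                     "sigma_log_area", "sigma_log_zmax", "sigma_obs_N", "sigma_obs_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.diversion_fraction <= 1:
            raise ValueError("diversion_fraction must be in [0, 1]")
        if len(self.inclusion_probs) != len(self.area_strata_m2) + 1:
            raise ValueError("need one inclusion probability per area stratum")


@dataclass
class SyntheticDataset:
    flow_table: pd.DataFrame
    reach_table: pd.DataFrame
    morphometry: pd.DataFrame
    observed: pd.DataFrame
    truth: pd.DataFrame          # per-lake generating quantities
    config: SimulationConfig


def generate_network(config: SimulationConfig, rng=None):
    """Build the flow and reach-attribute tables plus per-lake truth.

    Returns ``(flow_table, reach_table, truth)``; truth carries each lake's
    true total inputs, exports, flow, and whether a diversion was planted.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    edges: list[tuple] = []
    reaches: list[dict] = []
    truth_rows: list[dict] = []

    n_div = round(config.diversion_fraction * config.n_lakes)
    div_lakes = set(rng.choice(config.n_lakes, size=n_div, replace=False)) if n_div else set()

    next_id = 1
    for k in range(config.n_lakes):
        lake_id = f"L{k + 1}"
        n_int = int(rng.integers(config.internal_reaches[0], config.internal_reaches[1] + 1))
        n_inp = int(rng.integers(config.input_reaches[0], config.input_reaches[1] + 1))

        internal_ids = [f"R{next_id + i}" for i in range(n_int)]
        next_id += n_int

        # headwater tributaries: accumulated load over their drainage units
        trib = []
        for _ in range(n_inp):
            units = int(rng.integers(config.tributary_units[0], config.tributary_units[1] + 1))
            draws_N = rng.lognormal(config.mu_log_inc_N, config.sigma_log_inc_N, units)
            draws_P = rng.lognormal(config.mu_log_inc_P, config.sigma_log_inc_P, units)
            rid = f"R{next_id}"
            next_id += 1
            trib.append({
                "reach_id": rid, "lake_id": None,
                "total_load_N": float(draws_N.sum()),
                "incremental_load_N": float(draws_N[0]),
                "total_load_P": float(draws_P.sum()),
                "incremental_load_P": float(draws_P[0]),
                "flow_cfs": config.runoff_cfs_per_unit * units,
                "units": units,
            })
            # tributaries join a random internal reach (braided inputs allowed)
            edges.append((rid, internal_ids[int(rng.integers(0, n_int))]))

        inc_N = rng.lognormal(config.mu_log_inc_N, config.sigma_log_inc_N, n_int)
        inc_P = rng.lognormal(config.mu_log_inc_P, config.sigma_log_inc_P, n_int)

        # chain the internal reaches; loads and flow accumulate downstream
        internal_rows = []
        for i, rid in enumerate(internal_ids):
            if i + 1 < n_int:
                edges.append((rid, internal_ids[i + 1]))
            internal_rows.append({
                "reach_id": rid, "lake_id": lake_id,
                "incremental_load_N": float(inc_N[i]),
                "incremental_load_P": float(inc_P[i]),
                "units": 1,
            })

        joins: dict[str, list] = {rid: [] for rid in internal_ids}
        for t in trib:
            to = next(to for frm, to in edges if frm == t["reach_id"])
            joins[to].append(t)

        carry_N = carry_P = carry_flow = 0.0
        for i, row in enumerate(internal_rows):
            up_N = carry_N + sum(t["total_load_N"] for t in joins[row["reach_id"]])
            up_P = carry_P + sum(t["total_load_P"] for t in joins[row["reach_id"]])
            up_flow = carry_flow + sum(t["flow_cfs"] for t in joins[row["reach_id"]])
            row["total_load_N"] = up_N + row["incremental_load_N"]
            row["total_load_P"] = (up_P + row["incremental_load_P"]) * (1.0 - config.p_decay_per_reach)
            row["flow_cfs"] = up_flow + config.runoff_cfs_per_unit
            carry_N, carry_P, carry_flow = row["total_load_N"], row["total_load_P"], row["flow_cfs"]

        total_in_N = sum(t["total_load_N"] for t in trib) + float(inc_N.sum())
        total_in_P = sum(t["total_load_P"] for t in trib) + float(inc_P.sum())
        diverted = k in div_lakes
        if diverted:
            internal_rows[-1]["total_load_N"] *= (1.0 - config.diversion_loss)
            internal_rows[-1]["total_load_P"] *= (1.0 - config.diversion_loss)

        flow_m3yr = network.cfs_to_m3yr(internal_rows[-1]["flow_cfs"])
        truth_rows.append({
            "lake_id": lake_id,
            "total_in_N": total_in_N,
            "total_in_P": total_in_P,
            "export_N": internal_rows[-1]["total_load_N"],
            "export_P": internal_rows[-1]["total_load_P"],
            "flow_m3yr": flow_m3yr,
            "conc_in_N": network.load_to_concentration(total_in_N, flow_m3yr),
            "conc_in_P": network.load_to_concentration(total_in_P, flow_m3yr),
            "diverted": diverted,
        })
        reaches.extend(trib)
        reaches.extend(internal_rows)

        # a downstream external reach receives the lake's export
        rid = f"R{next_id}"
        next_id += 1
        edges.append((internal_ids[-1], rid))
        reaches.append({
            "reach_id": rid, "lake_id": None,
            "total_load_N": internal_rows[-1]["total_load_N"],
            "incremental_load_N": 0.0,
            "total_load_P": internal_rows[-1]["total_load_P"],
            "incremental_load_P": 0.0,
            "flow_cfs": internal_rows[-1]["flow_cfs"],
            "units": 0,
        })

    reach_table = pd.DataFrame(
        reaches, columns=["reach_id", "lake_id", "total_load_N", "incremental_load_N",
                          "total_load_P", "incremental_load_P", "flow_cfs", "units"],
    ).drop(columns="units")
    flow_table = pd.DataFrame(edges, columns=["from_reach", "to_reach"])
    truth = pd.DataFrame(truth_rows, columns=[
        "lake_id", "total_in_N", "total_in_P", "export_N", "export_P",
        "flow_m3yr", "conc_in_N", "conc_in_P", "diverted"])
    return flow_table, reach_table, truth


def generate_morphometry(config: SimulationConfig, lake_ids, rng=None) -> pd.DataFrame:
    """Lognormal area and maximum depth; conic volume area * zmax / 3."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = len(lake_ids)
    area = rng.lognormal(config.mu_log_area, config.sigma_log_area, n)
    zmax = np.maximum(1.0, rng.lognormal(config.mu_log_zmax, config.sigma_log_zmax, n))
    volume = area * zmax / 3.0
    return pd.DataFrame({
        "lake_id": np.asarray(lake_ids),
        "area_m2": area,
        "zmax_m": zmax,
        "volume_m3": volume,
    })


def assign_weights(config: SimulationConfig, morphometry: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Survey design: stratified inclusion by area, weights = 1/probability.

    Each lake enters the probability sample with its area stratum's
    inclusion probability (larger lakes oversampled); its design weight is
    the inverse of that probability.  Lakes outside the sample stand in for
    hand-selected reference sites: they carry observations and weights but
    ``is_probability_sample`` is False, so design-weighted estimates
    exclude them.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    stratum = np.searchsorted(np.asarray(config.area_strata_m2),
                              morphometry["area_m2"].to_numpy())
    probs = np.asarray(config.inclusion_probs)[stratum]
    is_prob = rng.random(len(morphometry)) < probs
    return pd.DataFrame({
        "lake_id": morphometry["lake_id"].to_numpy(),
        "design_weight": 1.0 / probs,
        "is_probability_sample": is_prob,
    })


def simulate_observations(lakes: pd.DataFrame, truth_N: InputOutputModelSpec,
                          truth_P: InputOutputModelSpec, sigma_N: float,
                          sigma_P: float, rng) -> pd.DataFrame:
    """Noisy summer concentrations from the truth models.

    ``lakes`` needs ``lake_id``, ``conc_in_N``, ``conc_in_P``, ``tau_yr``,
    ``z_mean_m``.  log10(observed) = log10(model prediction) + eps, eps ~
    N(0, sigma^2).  TP values below the detection limit are flagged; the
    substitution itself is the calibration stage's job.
    """
    usable = lakes.dropna(subset=["conc_in_N", "conc_in_P", "tau_yr", "z_mean_m"])
    usable = usable[(usable["tau_yr"] > 0) & (usable["z_mean_m"] > 0)
                    & (usable["conc_in_N"] > 0) & (usable["conc_in_P"] > 0)]
    tau = usable["tau_yr"].to_numpy()
    z = usable["z_mean_m"].to_numpy()
    pred_N = predict_concentration(truth_N, usable["conc_in_N"].to_numpy(), tau, z)
    pred_P = predict_concentration(truth_P, usable["conc_in_P"].to_numpy(), tau, z)
    n = len(usable)
    obs_TN = 10.0 ** (np.log10(pred_N) + rng.normal(0.0, sigma_N, n))
    obs_TP = 10.0 ** (np.log10(pred_P) + rng.normal(0.0, sigma_P, n))
    return pd.DataFrame({
        "lake_id": usable["lake_id"].to_numpy(),
        "obs_TN": obs_TN,
        "obs_TP": obs_TP,
        "true_TN": pred_N,
        "true_TP": pred_P,
        "below_detection_TP": obs_TP < TP_DETECTION_LIMIT,
    })


def end_to_end_fixture(config: SimulationConfig) -> SyntheticDataset:
    """Compose network, morphometry, weights and observations.

    All randomness flows from ``config.seed`` through a single generator,
    so identical configs give byte-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    flow_table, reach_table, truth = generate_network(config, rng)
    morphometry = generate_morphometry(config, truth["lake_id"], rng)
    weights = assign_weights(config, morphometry, rng)

    lakes = truth.merge(morphometry, on="lake_id")
    lakes["z_mean_m"] = network.mean_depth(lakes["volume_m3"], lakes["area_m2"])
    lakes["tau_yr"] = network.hydraulic_residence_time(lakes["volume_m3"], lakes["flow_m3yr"])
    truth = truth.assign(z_mean_m=lakes["z_mean_m"], tau_yr=lakes["tau_yr"])

    if len(lakes):
        observed = simulate_observations(lakes, config.truth_N, config.truth_P,
                                         config.sigma_obs_N, config.sigma_obs_P, rng)
        observed = observed.merge(weights, on="lake_id")
    else:
        observed = pd.DataFrame(columns=[
            "lake_id", "obs_TN", "obs_TP", "true_TN", "true_TP",
            "below_detection_TP", "design_weight", "is_probability_sample"])
    return SyntheticDataset(flow_table=flow_table, reach_table=reach_table,
                            morphometry=morphometry, observed=observed,
                            truth=truth, config=config)
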