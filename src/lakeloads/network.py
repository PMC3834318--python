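"""Flow-network aggregation of reach-level nutrient loads to lake budgets.

Reach predictions (total and incremental nitrogen/phosphorus loads in kg/yr,
flow in CFS) are carried on an NHDPlus-style directed flow table of
(from_reach, to_reach) pairs.  A lake is the set of reaches sharing a
waterbody id; its nutrient budget is assembled from the reaches immediately
upstream (inputs), the reaches inside it (incremental loads), and its
most-downstream internal reaches (outflows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Conversion from cubic feet per second to cubic metres per year
#: (0.0283168466 m3/ft3 x 31,556,926 s/yr, rounded).
CFS_TO_M3YR = 893_593.0

#: Nutrients carried on every reach table.
NUTRIENTS = ("N", "P")

REACH_COLUMNS = {
    "COMID": "reach_id",
    "WB_ID": "lake_id",
    "TOT_N_KGYR": "total_load_N",
    "INC_N_KGYR": "incremental_load_N",
    "TOT_P_KGYR": "total_load_P",
    "INC_P_KGYR": "incremental_load_P",
    "FLOW_CFS": "flow_cfs",
}


class LakeNotFoundError(KeyError):
    """Raised when a lake id has no reaches in the attribute table."""


class CyclicLakeTopologyError(ValueError):
    """Raised when a lake's internal reaches form a directed cycle."""


@dataclass
class LakeBudget:
    """Aggregated nutrient and water budget for one lake.

    Loads are kg/yr, flow is m3/yr, concentrations are mg/L.  Concentrations
    are NaN when the lake exports no water (``flow_m3yr == 0``).
    """

    lake_id: object
    upstream_in_N: float = 0.0
    upstream_in_P: float = 0.0
    incremental_in_N: float = 0.0
    incremental_in_P: float = 0.0
    total_in_N: float = 0.0
    total_in_P: float = 0.0
    export_N: float = 0.0
    export_P: float = 0.0
    flow_m3yr: float = 0.0
    conc_in_N: float = float("nan")
    conc_in_P: float = float("nan")
    conc_out_N: float = float("nan")
    conc_out_P: float = float("nan")

    @property
    def has_flow(self) -> bool:
        return self.flow_m3yr > 0


def cfs_to_m3yr(flow_cfs, factor: float = CFS_TO_M3YR):
    """Convert average-annual flow from CFS to m3/yr."""
    flow_cfs = np.asarray(flow_cfs, dtype=float)
    if np.any(flow_cfs < 0):
        raise ValueError("flow_cfs must be nonnegative")
    out = flow_cfs * factor
    return float(out) if out.ndim == 0 else out


def load_to_concentration(load_kg_yr, flow_m3yr):
    """Convert an annual load (kg/yr) and flow (m3/yr) to mg/L.

    kg/m3 = 1e6 mg / 1e3 L, so the kg/yr / m3/yr ratio is scaled by 1000
    (1 g/m3 == 1 mg/L).  Returns NaN where flow is not positive.
    """
    load = np.asarray(load_kg_yr, dtype=float)
    flow = np.asarray(flow_m3yr, dtype=float)
    out = np.where(flow > 0, 1000.0 * load / np.where(flow > 0, flow, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def hydraulic_residence_time(volume_m3, flow_m3yr):
    """Lake volume divided by annual throughflow, in years (NaN if flow <= 0)."""
    v = np.asarray(volume_m3, dtype=float)
    q = np.asarray(flow_m3yr, dtype=float)
    out = np.where(q > 0, v / np.where(q > 0, q, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def mean_depth(volume_m3, area_m2):
    """Lake volume divided by surface area, in metres (NaN if area <= 0)."""
    v = np.asarray(volume_m3, dtype=float)
    a = np.asarray(area_m2, dtype=float)
    out = np.where(a > 0, v / np.where(a > 0, a, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def _edge_maps(flow_table: pd.DataFrame, known_reaches: set | None = None):
    """Downstream and upstream adjacency from an edge table.

    Edges referencing reaches absent from the attribute table are kept in
    the maps (topology may legitimately extend past the study area); the
    caller decides whether a dangling endpoint matters.
    """
    downstream: dict = {}
    upstream: dict = {}
    for frm, to in zip(flow_table["from_reach"], flow_table["to_reach"]):
        if frm == to:
            raise ValueError(f"self-loop at reach {frm!r}")
        downstream.setdefault(frm, set()).add(to)
        upstream.setdefault(to, set()).add(frm)
    return downstream, upstream


def classify_lake_reaches(lake_id, reach_table: pd.DataFrame, flow_table: pd.DataFrame):
    """Split the network around one lake into internal, input and outflow reaches.

    internal  — reaches whose ``lake_id`` matches;
    inputs    — reaches outside the lake that flow directly into an internal
                reach (FromComIDs of internal reaches, minus internal ones);
    outflows  — internal reaches with at least one downstream connection
                outside the lake, or with no downstream connection at all
                (a terminal reach still exports).

    Returns ``(internal_ids, input_ids, outflow_internal_ids)`` as sets.
    """
    internal = set(reach_table.loc[reach_table["lake_id"] == lake_id, "reach_id"])
    if not internal:
        raise LakeNotFoundError(f"lake not found: {lake_id!r}")

    downstream, upstream = _edge_maps(flow_table)

    sub = nx.DiGraph()
    sub.add_nodes_from(internal)
    for frm, tos in downstream.items():
        if frm in internal:
            sub.add_edges_from((frm, to) for to in tos if to in internal)
    if not nx.is_directed_acyclic_graph(sub):
        raise CyclicLakeTopologyError(f"cyclic lake topology: {lake_id!r}")

    known = set(reach_table["reach_id"])
    inputs = set()
    for comid in internal:
        for frm in upstream.get(comid, ()):
            if frm in internal:
                continue
            if frm not in known:
                logger.warning("dangling upstream reach %r for lake %r skipped", frm, lake_id)
                continue
            inputs.add(frm)

    outflows = set()
    for comid in internal:
        tos = downstream.get(comid, set())
        if not tos or any(to not in internal for to in tos):
            outflows.add(comid)

    return internal, inputs, outflows


def aggregate_lake_budget(lake_id, reach_table: pd.DataFrame, flow_table: pd.DataFrame,
                          cfs_factor: float = CFS_TO_M3YR) -> LakeBudget:
    """Assemble a :class:`LakeBudget` from reach predictions.

    Upstream inputs sum the total loads of the input reaches; incremental
    inputs sum the incremental loads of the internal reaches; exports sum
    the total loads of the outflow reaches; flow sums the outflow CFS and
    converts to m3/yr.  Concentrations are load/flow in mg/L and NaN when
    the lake exports no water.
    """
    internal, inputs, outflows = classify_lake_reaches(lake_id, reach_table, flow_table)
    idx = reach_table.set_index("reach_id")

    budget = LakeBudget(lake_id=lake_id)
    in_rows = idx.loc[sorted(inputs, key=repr)] if inputs else None
    internal_rows = idx.loc[sorted(internal, key=repr)]
    out_rows = idx.loc[sorted(outflows, key=repr)]

    budget.flow_m3yr = cfs_to_m3yr(float(out_rows["flow_cfs"].sum()), cfs_factor)
    for nut in NUTRIENTS:
        up = float(in_rows[f"total_load_{nut}"].sum()) if in_rows is not None else 0.0
        inc = float(internal_rows[f"incremental_load_{nut}"].sum())
        exp = float(out_rows[f"total_load_{nut}"].sum())
        setattr(budget, f"upstream_in_{nut}", up)
        setattr(budget, f"incremental_in_{nut}", inc)
        setattr(budget, f"total_in_{nut}", up + inc)
        setattr(budget, f"export_{nut}", exp)
        setattr(budget, f"conc_in_{nut}", load_to_concentration(up + inc, budget.flow_m3yr))
        setattr(budget, f"conc_out_{nut}", load_to_concentration(exp, budget.flow_m3yr))
    if not budget.has_flow:
        logger.info("lake %r has zero outflow; concentrations undefined", lake_id)
    return budget


def aggregate_all_lakes(reach_table: pd.DataFrame, flow_table: pd.DataFrame,
                        cfs_factor: float = CFS_TO_M3YR) -> pd.DataFrame:
    """Aggregate budgets for every lake present in the reach table."""
    lake_ids = reach_table["lake_id"].dropna().unique()
    budgets = [aggregate_lake_budget(lk, reach_table, flow_table, cfs_factor)
               for lk in lake_ids]
    return budgets_to_frame(budgets)


def budgets_to_frame(budgets) -> pd.DataFrame:
    """One row per LakeBudget; column order matches the dataclass."""
    return pd.DataFrame([vars(b) for b in budgets])


def mass_balance_filter(budgets: pd.DataFrame, rel_tol: float = 1e-6) -> pd.DataFrame:
    """Keep lakes whose nitrogen budget balances (N_in == N_out).

    The regional SPARROW model applies no in-lake nitrogen decay, so any
    imbalance indicates a hydrologic artefact (e.g. a diversion); such lakes
    are excluded.  Retains rows with ``|total_in_N - export_N| <= rel_tol *
    total_in_N`` and ``total_in_N > 0``; order preserved.
    """
    tin = budgets["total_in_N"].to_numpy(dtype=float)
    out = budgets["export_N"].to_numpy(dtype=float)
    keep = (tin > 0) & (np.abs(tin - out) <= rel_tol * tin)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("mass-balance filter dropped %d of %d lakes", dropped, len(budgets))
    return budgets.loc[keep].copy()


def attach_morphometry(budgets: pd.DataFrame, morphometry: pd.DataFrame) -> pd.DataFrame:
    """Join lake morphometry and derive mean depth and residence time.

    Adds ``z_mean_m`` (volume/area) and ``tau_yr`` (volume/flow).  Lakes
    missing morphometry, with zero flow, or with nonpositive area keep NaN
    in the derived columns and are excluded by downstream dropna steps.
    """
    merged = budgets.merge(
        morphometry[["lake_id", "area_m2", "volume_m3", "zmax_m"]],
        on="lake_id", how="left",
    )
    merged["z_mean_m"] = mean_depth(merged["volume_m3"], merged["area_m2"])
    merged["tau_yr"] = hydraulic_residence_time(merged["volume_m3"], merged["flow_m3yr"])
    return merged
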