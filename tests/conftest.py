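import numpy as np
import pandas as pd
import pytest

from lakeloads import synth
from lakeloads.network import CFS_TO_M3YR


def make_reach_table(rows):
    """rows: (reach_id, lake_id, tot_N, inc_N, tot_P, inc_P, flow_cfs)."""
    return pd.DataFrame(rows, columns=[
        "reach_id", "lake_id", "total_load_N", "incremental_load_N",
        "total_load_P", "incremental_load_P", "flow_cfs"])


def make_flow_table(edges):
    return pd.DataFrame(edges, columns=["from_reach", "to_reach"])


@pytest.fixture
def simple_lake():
    """One lake {A, B} fed by X, draining to C: the worked join example."""
    reaches = make_reach_table([
        ("X", None, 100.0, 100.0, 10.0, 10.0, 2.0),
        ("A", "lk", 110.0, 10.0, 11.0, 1.0, 2.5),
        ("B", "lk", 115.0, 5.0, 11.5, 0.5, 3.0),
        ("C", None, 115.0, 0.0, 11.5, 0.0, 3.0),
    ])
    edges = make_flow_table([("X", "A"), ("A", "B"), ("B", "C")])
    return reaches, edges


def random_dag_network(rng, n_reaches=200, n_lakes=12):
    """Random acyclic network with random lake membership, for oracle checks.

    Nodes are topologically ordered by construction (edges only run from a
    lower to a higher index), so any lake's internal subgraph is acyclic.
    """
    ids = [f"r{i}" for i in range(n_reaches)]
    edges = []
    for j in range(1, n_reaches):
        for i in rng.choice(j, size=min(j, rng.integers(0, 3)), replace=False):
            edges.append((ids[i], ids[j]))
    lake_of = {}
    membership = rng.integers(-1, n_lakes, size=n_reaches)
    for i, m in enumerate(membership):
        if m >= 0:
            lake_of[ids[i]] = f"lake{m}"
    reaches = make_reach_table([
        (ids[i], lake_of.get(ids[i]),
         float(rng.uniform(0, 100)), float(rng.uniform(0, 10)),
         float(rng.uniform(0, 10)), float(rng.uniform(0, 1)),
         float(rng.uniform(0, 5)))
        for i in range(n_reaches)])
    return reaches, make_flow_table(edges)


def brute_force_budget(lake_id, reach_table, flow_table):
    """Independent budget oracle: enumerate every edge crossing the lake
    boundary directly from the raw tables, no set algebra shared with the
    implementation."""
    internal = {r.reach_id for r in reach_table.itertuples() if r.lake_id == lake_id}
    rows = {r.reach_id: r for r in reach_table.itertuples()}
    inputs, outflow = set(), set()
    for e in flow_table.itertuples():
        if e.to_reach in internal and e.from_reach not in internal \
                and e.from_reach in rows:
            inputs.add(e.from_reach)
        if e.from_reach in internal and e.to_reach not in internal:
            outflow.add(e.from_reach)
    has_downstream = set(flow_table["from_reach"])
    outflow |= {r for r in internal if r not in has_downstream}
    budget = {"lake_id": lake_id, "flow_m3yr": CFS_TO_M3YR * sum(
        rows[r].flow_cfs for r in outflow)}
    for nut in ("N", "P"):
        up = sum(getattr(rows[r], f"total_load_{nut}") for r in inputs)
        inc = sum(getattr(rows[r], f"incremental_load_{nut}") for r in internal)
        budget[f"upstream_in_{nut}"] = up
        budget[f"incremental_in_{nut}"] = inc
        budget[f"total_in_{nut}"] = up + inc
        budget[f"export_{nut}"] = sum(
            getattr(rows[r], f"total_load_{nut}") for r in outflow)
    return budget


@pytest.fixture(scope="session")
def default_dataset():
    """One 500-lake synthetic dataset under default study conditions."""
    return synth.end_to_end_fixture(synth.SimulationConfig(n_lakes=500, seed=11))


def calibration_frame(dataset, nutrient):
    """Calibration table straight from a SyntheticDataset's truth record."""
    t = dataset.truth.merge(dataset.observed, on="lake_id")
    return pd.DataFrame({
        "lake_id": t["lake_id"],
        "obs": t["obs_TN" if nutrient == "N" else "obs_TP"],
        "conc_in": t[f"conc_in_{nutrient}"],
        "conc_out": 1000.0 * t[f"export_{nutrient}"] / t["flow_m3yr"],
        "tau_yr": t["tau_yr"],
        "z_mean_m": t["z_mean_m"],
    })
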