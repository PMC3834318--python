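"""Flow-network classification and lake-budget aggregation."""

import numpy as np
import pandas as pd
import pytest

from lakeloads import network
from lakeloads.network import (
    CFS_TO_M3YR, CyclicLakeTopologyError, LakeNotFoundError,
    aggregate_lake_budget, cfs_to_m3yr, classify_lake_reaches,
    hydraulic_residence_time, load_to_concentration, mass_balance_filter,
    mean_depth,
)

from conftest import (brute_force_budget, make_flow_table, make_reach_table,
                      random_dag_network)


class TestClassifyLakeReaches:
    def test_chain_lake(self, simple_lake):
        reaches, edges = simple_lake
        internal, inputs, outflows = classify_lake_reaches("lk", reaches, edges)
        assert internal == {"A", "B"}
        assert inputs == {"X"}
        assert outflows == {"B"}

    def test_isolated_lake_terminal_reach_is_outflow(self):
        reaches = make_reach_table([("A", "lk", 7, 7, 1, 1, 1.0)])
        internal, inputs, outflows = classify_lake_reaches(
            "lk", reaches, make_flow_table([]))
        assert (internal, inputs, outflows) == ({"A"}, set(), {"A"})

    def test_braided_inputs(self):
        reaches = make_reach_table([
            ("X", None, 1, 1, 1, 1, 1), ("Y", None, 1, 1, 1, 1, 1),
            ("A", "lk", 1, 1, 1, 1, 1), ("B", "lk", 1, 1, 1, 1, 1)])
        edges = make_flow_table([("X", "A"), ("Y", "B"), ("A", "B")])
        _, inputs, outflows = classify_lake_reaches("lk", reaches, edges)
        assert inputs == {"X", "Y"}
        assert outflows == {"B"}

    def test_unknown_lake(self, simple_lake):
        reaches, edges = simple_lake
        with pytest.raises(LakeNotFoundError, match="lake not found"):
            classify_lake_reaches("nope", reaches, edges)

    def test_internal_cycle_rejected(self):
        reaches = make_reach_table([
            ("A", "lk", 1, 1, 1, 1, 1), ("B", "lk", 1, 1, 1, 1, 1)])
        edges = make_flow_table([("A", "B"), ("B", "A")])
        with pytest.raises(CyclicLakeTopologyError):
            classify_lake_reaches("lk", reaches, edges)

    def test_dangling_upstream_reference_skipped(self, simple_lake):
        reaches, edges = simple_lake
        edges = pd.concat([edges, make_flow_table([("ghost", "A")])])
        _, inputs, _ = classify_lake_reaches("lk", reaches, edges)
        assert "ghost" not in inputs

    def test_partition_properties(self):
        rng = np.random.default_rng(5)
        reaches, edges = random_dag_network(rng, 120, 8)
        for lake_id in reaches["lake_id"].dropna().unique():
            internal, inputs, outflows = classify_lake_reaches(lake_id, reaches, edges)
            assert inputs.isdisjoint(internal)
            assert outflows <= internal


class TestAggregation:
    def test_hand_summed_budget(self, simple_lake):
        reaches, edges = simple_lake
        b = aggregate_lake_budget("lk", reaches, edges)
        assert b.upstream_in_N == 100.0
        assert b.incremental_in_N == 15.0
        assert b.total_in_N == 115.0
        assert b.export_N == 115.0
        assert b.flow_m3yr == pytest.approx(3.0 * CFS_TO_M3YR)
        assert b.conc_in_N == pytest.approx(1000 * 115.0 / (3.0 * CFS_TO_M3YR))

    def test_single_reach_conservation(self):
        reaches = make_reach_table([("A", "lk", 7, 7, 1, 1, 1.0)])
        b = aggregate_lake_budget("lk", reaches, make_flow_table([]))
        assert b.total_in_N == b.export_N == 7.0

    def test_two_outflows_summed(self):
        reaches = make_reach_table([
            ("A", "lk", 6, 6, 1, 1, 1.0), ("B", "lk", 4, 4, 1, 1, 2.0),
            ("C", None, 10, 0, 2, 0, 3.0)])
        edges = make_flow_table([("A", "C"), ("B", "C")])
        b = aggregate_lake_budget("lk", reaches, edges)
        assert b.flow_m3yr == pytest.approx(3.0 * CFS_TO_M3YR)
        assert b.export_N == 10.0

    def test_zero_flow_concentrations_undefined(self):
        reaches = make_reach_table([("A", "lk", 7, 7, 1, 1, 0.0)])
        b = aggregate_lake_budget("lk", reaches, make_flow_table([]))
        assert not b.has_flow
        assert np.isnan(b.conc_in_N) and np.isnan(b.conc_out_P)

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            reaches, edges = random_dag_network(rng)
            for lake_id in reaches["lake_id"].dropna().unique():
                got = aggregate_lake_budget(lake_id, reaches, edges)
                want = brute_force_budget(lake_id, reaches, edges)
                for key, val in want.items():
                    if key == "lake_id":
                        continue
                    assert getattr(got, key) == pytest.approx(val, rel=1e-12), \
                        (lake_id, key)

    def test_adding_input_reach_never_decreases_total_in(self, simple_lake):
        reaches, edges = simple_lake
        before = aggregate_lake_budget("lk", reaches, edges).total_in_N
        reaches2 = pd.concat([reaches, make_reach_table(
            [("Y", None, 50.0, 50.0, 5.0, 5.0, 1.0)])], ignore_index=True)
        edges2 = pd.concat([edges, make_flow_table([("Y", "B")])])
        after = aggregate_lake_budget("lk", reaches2, edges2).total_in_N
        assert after >= before


class TestUnitConversions:
    def test_cfs_constant(self):
        assert cfs_to_m3yr(0.0) == 0.0
        assert cfs_to_m3yr(1.0) == 893_593.0
        # independent unit arithmetic: ft3->m3 times seconds per year
        assert 0.0283168466 * 31_556_926 == pytest.approx(893_593, abs=0.5)

    def test_cfs_negative_rejected(self):
        with pytest.raises(ValueError):
            cfs_to_m3yr(-1.0)

    @pytest.mark.parametrize("load,flow,expect", [
        (1000.0, 1e6, 1.0),
        (0.0, 1e6, 0.0),
        (115.0, 893_593.0, 0.12869),
    ])
    def test_load_to_concentration(self, load, flow, expect):
        assert load_to_concentration(load, flow) == pytest.approx(expect, abs=1e-5)

    def test_concentration_undefined_at_zero_flow(self):
        assert np.isnan(load_to_concentration(10.0, 0.0))

    def test_residence_time_and_mean_depth(self):
        assert hydraulic_residence_time(1e6, 1e6) == 1.0
        assert mean_depth(1e6, 5e5) == 2.0
        # boundary of the short residence-time class
        assert hydraulic_residence_time(2e5, 5e6) == pytest.approx(0.04)
        assert np.isnan(hydraulic_residence_time(1e6, 0.0))
        assert np.isnan(mean_depth(1e6, 0.0))


class TestMassBalanceFilter:
    def test_balanced_retained_unbalanced_dropped(self):
        budgets = pd.DataFrame({
            "lake_id": ["a", "b"],
            "total_in_N": [100.0, 100.0],
            "export_N": [100.0, 80.0],
        })
        kept = mass_balance_filter(budgets)
        assert list(kept["lake_id"]) == ["a"]

    def test_order_preserved_and_zero_input_dropped(self):
        budgets = pd.DataFrame({
            "lake_id": ["a", "b", "c"],
            "total_in_N": [1.0, 0.0, 2.0],
            "export_N": [1.0, 0.0, 2.0],
        })
        assert list(mass_balance_filter(budgets)["lake_id"]) == ["a", "c"]

    def test_planted_diversions_filtered_exactly(self):
        from lakeloads import synth
        cfg = synth.SimulationConfig(n_lakes=50, seed=7, diversion_fraction=0.1)
        ds = synth.end_to_end_fixture(cfg)
        budgets = network.aggregate_all_lakes(ds.reach_table, ds.flow_table)
        kept = mass_balance_filter(budgets)
        assert len(kept) == 45
        assert set(budgets["lake_id"]) - set(kept["lake_id"]) == \
            set(ds.truth.loc[ds.truth["diverted"], "lake_id"])
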