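"""ACERs, dominance frontier vs brute force, threshold decisions."""

import copy

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ruraldce as rd
from ruraldce import config as cfgmod
from ruraldce.cea import run_sensitivity
from ruraldce.pipeline import cea_from_published


def published_points():
    pub = cfgmod.load_fixture("published_cea")["packages"]
    return [rd.CEAPoint(int(pid), r["cost_5yr_cash"], r["qalys_5yr"])
            for pid, r in pub.items()]


class TestAverageCer:
    def test_published_package4(self):
        assert rd.average_cer(669_983, 461) == pytest.approx(1454, abs=1)

    def test_zero_cost(self):
        assert rd.average_cer(0.0, 10.0) == 0.0

    def test_published_package11(self):
        assert rd.average_cer(536_504, 336) == pytest.approx(1597, abs=1)

    def test_nonpositive_qalys_rejected(self):
        with pytest.raises(ValueError, match="QALY"):
            rd.average_cer(100.0, 0.0)


def greedy_hull_frontier(points):
    """Independent oracle: gift-wrap the lowest-ICER chain from the origin."""
    remaining = [p for p in points if p.qalys > 0]
    frontier = []
    c, q = 0.0, 0.0
    while True:
        cands = [p for p in remaining if p.qalys > q]
        if not cands:
            break
        best = min(cands, key=lambda p: ((p.cost - c) / (p.qalys - q),
                                         -p.qalys, p.package_id))
        frontier.append(best.package_id)
        c, q = best.cost, best.qalys
    return frontier


class TestDominanceFrontier:
    def test_published_inputs_frontier_is_4_then_1(self):
        table = rd.dominance_frontier(published_points())
        frontier = table[table["status"] == "frontier"]
        assert sorted(frontier["package_id"]) == [1, 4]
        icers = frontier.set_index("package_id")["icer"]
        assert icers[4] == pytest.approx(1454, abs=1)
        assert icers[4] == pytest.approx(669_983 / 461, rel=1e-9)
        assert icers[1] == pytest.approx(
            (2_836_963 - 669_983) / (534 - 461), rel=1e-9)

    def test_single_package_icer_equals_acer(self):
        table = rd.dominance_frontier([rd.CEAPoint(1, 500.0, 10.0)])
        row = table.iloc[0]
        assert row["status"] == "frontier"
        assert row["icer"] == row["acer"] == 50.0

    def test_middle_point_above_chord_extendedly_dominated(self):
        # the middle option lies above the segment joining its neighbours
        pts = [rd.CEAPoint(1, 100.0, 10.0), rd.CEAPoint(2, 240.0, 20.0),
               rd.CEAPoint(3, 350.0, 30.0)]
        table = rd.dominance_frontier(pts).set_index("package_id")
        assert table.loc[2, "status"] == "extendedly dominated"
        assert table.loc[1, "status"] == "frontier"
        assert table.loc[3, "status"] == "frontier"

    def test_exact_collinear_ties_keep_highest_qalys(self):
        # with exactly equal ICERs a strictly increasing chain cannot hold
        # more than one of the tied points; the most effective one survives
        pts = [rd.CEAPoint(1, 100.0, 10.0), rd.CEAPoint(2, 200.0, 20.0),
               rd.CEAPoint(3, 300.0, 30.0)]
        table = rd.dominance_frontier(pts).set_index("package_id")
        assert (table["status"] == "frontier").sum() == 1
        assert table.loc[3, "status"] == "frontier"

    def test_strong_dominance_labelled(self):
        pts = [rd.CEAPoint(1, 100.0, 10.0), rd.CEAPoint(2, 150.0, 9.0)]
        table = rd.dominance_frontier(pts).set_index("package_id")
        assert table.loc[2, "status"] == "strongly dominated"

    def test_duplicate_points_lower_id_wins(self):
        pts = [rd.CEAPoint(7, 100.0, 10.0), rd.CEAPoint(3, 100.0, 10.0)]
        table = rd.dominance_frontier(pts).set_index("package_id")
        assert table.loc[3, "status"] == "frontier"
        assert table.loc[7, "status"] == "strongly dominated"

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(1, 11)
            pts = [
                rd.CEAPoint(i + 1, float(rng.uniform(0, 1000)),
                            float(rng.uniform(0.1, 100)))
                for i in range(n)
            ]
            table = rd.dominance_frontier(pts)
            ours = sorted(table[table["status"] == "frontier"]["package_id"])
            oracle = sorted(greedy_hull_frontier(pts))
            assert ours == oracle, f"mismatch on {pts}"

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0.0, 1e6), st.floats(0.1, 1e3)),
            min_size=1, max_size=10,
        )
    )
    def test_matches_bruteforce_property(self, pairs):
        pts = [rd.CEAPoint(i + 1, c, q) for i, (c, q) in enumerate(pairs)]
        table = rd.dominance_frontier(pts)
        ours = sorted(table[table["status"] == "frontier"]["package_id"])
        assert ours == sorted(greedy_hull_frontier(pts))

    def test_frontier_icers_strictly_increase(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = [rd.CEAPoint(i, float(rng.uniform(0, 1e6)),
                               float(rng.uniform(1, 500)))
                   for i in range(8)]
            table = rd.dominance_frontier(pts)
            icers = table[table["status"] == "frontier"].sort_values(
                "qalys")["icer"].to_numpy()
            assert np.all(np.diff(icers) > 0)


class TestThresholdDecision:
    def test_published_counts_and_optimum(self):
        table, decision, n_under_5 = cea_from_published(5, "cash")
        assert n_under_5 == 7
        assert decision.optimal_package == 4
        assert decision.optimal_icer == pytest.approx(1454, abs=1)
        _, _, n_under_30 = cea_from_published(30, "cash")
        assert n_under_30 == 3

    def test_threshold_below_every_icer(self):
        table = rd.dominance_frontier(published_points())
        decision = rd.threshold_decision(table, threshold=100.0)
        assert decision.optimal_package is None

    def test_threshold_monotone(self):
        table = rd.dominance_frontier(published_points())
        prev: set = set()
        for thr in (1000.0, 2000.0, 4000.0, 10_000.0, 100_000.0):
            d = rd.threshold_decision(table, thr)
            ids = set(d.under_threshold_ids)
            assert prev <= ids
            prev = ids

    def test_nonpositive_threshold_rejected(self):
        table = rd.dominance_frontier(published_points())
        with pytest.raises(ValueError, match="threshold"):
            rd.threshold_decision(table, 0.0)


class TestSensitivity:
    @staticmethod
    def _pipeline_fn(cfg):
        # synthetic model in which package 1 strictly dominates the rest;
        # perturbations rescale costs but cannot change the ranking
        scale = 1 + cfg["economics"]["discount_rate"]
        pts = [rd.CEAPoint(1, 100.0 * scale, 50.0),
               rd.CEAPoint(2, 220.0 * scale, 40.0),
               rd.CEAPoint(3, 340.0 * scale, 30.0)]
        return rd.dominance_frontier(pts), 1e9

    def test_empty_scenario_list_runs_base_only(self, base_config):
        df = run_sensitivity(base_config, [], self._pipeline_fn)
        assert len(df) == 1
        assert df["scenario"].iloc[0] == "base case"

    def test_dominant_package_selected_in_every_scenario(self, base_config):
        scenarios = [
            {"name": "high discount", "param": "discount_rate", "value": 0.05},
            {"name": "low discount", "param": "discount_rate", "value": 0.01},
            {"name": "high attrition", "param": "attrition", "value": 0.05},
            {"name": "depreciation", "param": "accounting_method",
             "value": "depreciation"},
        ]
        df = run_sensitivity(base_config, scenarios, self._pipeline_fn)
        assert (df["optimal_package"] == 1).all()

    def test_unknown_parameter_rejected(self, base_config):
        with pytest.raises(KeyError, match="unknown"):
            cfgmod.apply_scenario(base_config,
                                  {"name": "x", "param": "nope", "value": 1})

    def test_utility_shift_moves_mean_by_sd(self, base_config):
        cfg = cfgmod.apply_scenario(
            base_config,
            {"name": "edu +1sd", "param": "utility_shift",
             "component": "education:one_year_wait", "value": 1.0},
        )
        shifted = cfgmod.parameter_table(cfg)
        base = cfgmod.parameter_table(base_config)
        assert shifted.coef("education:one_year_wait")[0] == pytest.approx(
            base.coef("education:one_year_wait")[0] + 0.59)
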