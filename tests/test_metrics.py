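"""Summary statistics, clustering indices, earnings splits, regressions,
and tidy CSV round-trip fidelity."""

import math

import numpy as np
import pandas as pd
import pytest

from coopbots import (
    Action,
    Condition,
    HumanModelParams,
    NodeKind,
    SessionConfig,
    clustering_indices,
    cooperation_fraction,
    decisions_frame,
    earnings_by_behavior,
    fit_cooperation_model,
    run_session,
    trend_model,
)
from coopbots.base import DataError
from coopbots.io import edges_frame, options_frame, rounds_frame, strategy_usage_frame
from coopbots.metrics import condition_summary
from coopbots.network import Network


def _net(humans, edges, bots=()):
    net = Network()
    for i in humans:
        net.add_node(i, NodeKind.HUMAN)
    for i in bots:
        net.add_node(i, NodeKind.BOT)
    net.g.add_edges_from(edges)
    return net


class TestCooperationFraction:
    def test_counting_and_recount_oracle(self, no_bot_session):
        res = no_bot_session
        for rec in res.rounds:
            frac = cooperation_fraction(rec, res.humans)
            recount = sum(rec.actions[h] == Action.C for h in res.humans) / len(res.humans)
            assert frac == recount

    def test_extremes_and_mixed(self, no_bot_session):
        rec = no_bot_session.rounds[0]
        all_c = dict(rec.actions)
        rec_all_c = type(rec)(**{**rec.__dict__, "actions": {h: Action.C for h in all_c}})
        assert cooperation_fraction(rec_all_c, no_bot_session.humans) == 1.0
        nine_c = {h: (Action.C if i < 9 else Action.D) for i, h in enumerate(sorted(all_c))}
        rec_nine = type(rec)(**{**rec.__dict__, "actions": nine_c})
        assert cooperation_fraction(rec_nine, no_bot_session.humans) == pytest.approx(0.5625)

    def test_zero_humans_is_an_error(self, no_bot_session):
        with pytest.raises(DataError):
            cooperation_fraction(no_bot_session.rounds[0], [])


class TestClusteringIndices:
    def test_all_cooperators_gives_unit_tie_fraction_and_undefined_assortativity(self):
        net = _net(range(4), [(0, 1), (1, 2), (2, 3)])
        actions = {i: Action.C for i in range(4)}
        cc, assort = clustering_indices(net, actions)
        assert cc == 1.0
        assert math.isnan(assort)

    def test_segregated_blocks_have_assortativity_one(self):
        net = _net(range(6), [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5)])
        actions = {0: Action.C, 1: Action.C, 2: Action.C, 3: Action.D, 4: Action.D, 5: Action.D}
        cc, assort = clustering_indices(net, actions)
        assert cc == pytest.approx(0.6)
        assert assort == pytest.approx(1.0)

    def test_five_node_fixture_matches_hand_computed_assortativity(self):
        # path 0-1-2-3-4 with actions C,C,C,D,D: mixing matrix gives
        # e_CC=.5, e_DD=.25, cross=.25 -> r = (.75-.53125)/(1-.53125) = 7/15
        net = _net(range(5), [(0, 1), (1, 2), (2, 3), (3, 4)])
        actions = {0: Action.C, 1: Action.C, 2: Action.C, 3: Action.D, 4: Action.D}
        cc, assort = clustering_indices(net, actions)
        assert cc == pytest.approx(0.5)
        assert assort == pytest.approx(7 / 15)

    def test_no_human_ties_flagged_as_missing(self):
        net = _net(range(3), [])
        actions = {i: Action.D for i in range(3)}
        cc, assort = clustering_indices(net, actions)
        assert math.isnan(cc) and math.isnan(assort)

    def test_bot_ties_excluded_from_human_subgraph(self):
        net = _net(range(3), [(0, 1), (0, 3), (1, 3), (2, 3)], bots=(3,))
        actions = {0: Action.C, 1: Action.C, 2: Action.D, 3: Action.C}
        cc, _ = clustering_indices(net, actions)
        assert cc == 1.0  # only the 0-1 human tie counts


class TestEarningsByBehavior:
    def test_all_defect_session_has_no_cooperator_series(self):
        params = HumanModelParams(p0=0.0, b_intercept=-50.0, b_prev=0.0, b_round=0.0)
        res = run_session(SessionConfig(human_params=params, seed=8))
        table = earnings_by_behavior(res)
        assert table["mean_earnings_cooperators"].isna().all()
        assert table["mean_earnings_defectors"].notna().all()

    def test_group_means_recompute_from_tidy_csv(self, disengaged_session, tmp_path):
        res = disengaged_session
        table = earnings_by_behavior(res)
        tidy = rounds_frame(res)
        path = tmp_path / "rounds.csv"
        tidy.to_csv(path, index=False)
        back = pd.read_csv(path)
        humans = back[back["kind"] == "human"]
        for _, row in table.iterrows():
            sub = humans[humans["round"] == row["round"]]
            for action, col in [("C", "mean_earnings_cooperators"), ("D", "mean_earnings_defectors")]:
                grp = sub[sub["action"] == action]["cum_earnings"]
                if grp.empty:
                    assert math.isnan(row[col])
                else:
                    assert row[col] == pytest.approx(grp.mean())


class TestTidyIO:
    def test_round_trip_preserves_fractions_and_edges(self, no_bot_session, tmp_path):
        res = no_bot_session
        rounds = rounds_frame(res)
        edges = edges_frame(res)
        p1, p2 = tmp_path / "r.csv", tmp_path / "e.csv"
        rounds.to_csv(p1, index=False)
        edges.to_csv(p2, index=False)
        rounds_back = pd.read_csv(p1)
        edges_back = pd.read_csv(p2)
        for rec in res.rounds:
            sub = rounds_back[(rounds_back["round"] == rec.round) & (rounds_back["kind"] == "human")]
            assert (sub["action"] == "C").mean() == cooperation_fraction(rec, res.humans)
            esub = edges_back[edges_back["round"] == rec.round]
            assert (
                sorted(zip(esub["node_a"], esub["node_b"])) == sorted(rec.edge_list)
            )

    def test_options_frame_accepted_flags_match_records(self, disengaged_session):
        res = disengaged_session
        frame = options_frame(res)
        n_accepted = sum(len(r.options_accepted) for r in res.rounds)
        assert frame["accepted"].sum() == n_accepted
        assert len(frame) == sum(len(r.options_issued) for r in res.rounds)

    def test_strategy_usage_frame_matches_branch_counts(self, mixed_session):
        frame = strategy_usage_frame(mixed_session)
        totals = frame[["n_self_rewire", "n_disengage_options", "n_engage_options"]].sum()
        expected = np.sum([r.mixed_branch_counts for r in mixed_session.rounds], axis=0)
        assert list(totals) == list(expected)

    def test_condition_summary_round_count_and_ranges(self, no_bot_session, disengaged_session):
        summary = condition_summary([no_bot_session, disengaged_session])
        assert set(summary["condition"]) == {"no_bot", "disengaged"}
        assert summary["round"].max() == 30
        assert summary["mean_coop_fraction"].between(0, 1).all()


class TestTrendModel:
    @staticmethod
    def _synthetic_decisions(slope, n_sessions=12, n_rounds=30, n_subjects=16, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sessions):
            session_effect = rng.normal(0, 0.3)
            for subj in range(n_subjects):
                for t in range(1, n_rounds + 1):
                    p = 1 / (1 + np.exp(-(0.4 + session_effect + slope * t)))
                    rows.append(
                        {
                            "session": s,
                            "condition": "synthetic",
                            "subject": subj,
                            "round": t,
                            "coop": int(rng.random() < p),
                        }
                    )
        return pd.DataFrame(rows)

    def test_zero_slope_interval_covers_zero_in_most_replicates(self):
        covered = 0
        n_rep = 40
        for rep in range(n_rep):
            data = self._synthetic_decisions(0.0, n_sessions=8, seed=100 + rep)
            est = trend_model(data).estimates["synthetic"]
            if est.ci_low <= 0.0 <= est.ci_high:
                covered += 1
        assert covered / n_rep >= 0.9

    def test_known_positive_slope_recovered_within_three_se(self):
        data = self._synthetic_decisions(0.05, n_sessions=16, seed=50)
        est = trend_model(data).estimates["synthetic"]
        assert est.converged
        assert abs(est.slope - 0.05) < 3 * est.se

    def test_condition_trend_orientation_under_calibrated_defaults(self):
        results = []
        for cond in (Condition.NO_BOT, Condition.DISENGAGED_INT):
            for s in range(16):
                results.append(run_session(SessionConfig(condition=cond, seed=900 + s)))
        tm = trend_model(decisions_frame(results))
        assert tm.method == "logit_cluster_cr"
        assert tm.estimates["no_bot"].slope < 0
        assert tm.estimates["disengaged"].slope > 0

    def test_too_few_sessions_is_an_error(self):
        data = self._synthetic_decisions(0.0, n_sessions=1)
        with pytest.raises(DataError):
            trend_model(data)


class TestCooperationModelRecovery:
    def test_generating_coefficients_recovered_within_confidence_intervals(self):
        params = HumanModelParams()
        results = []
        for i, cond in enumerate(
            (Condition.NO_BOT, Condition.RANDOM_INT, Condition.DISENGAGED_INT)
        ):
            for s in range(16):
                results.append(
                    run_session(SessionConfig(condition=cond, human_params=params, seed=1200 + 100 * i + s))
                )
        fit = fit_cooperation_model(decisions_frame(results))
        ci = fit.conf_int()
        truth = {
            "prev_coop": params.b_prev,
            "k": params.b_degree,
            "c": params.b_coop,
            "kc": params.b_inter,
            "round": params.b_round,
        }
        for name, true_val in truth.items():
            low, high = ci.loc[name]
            assert low <= true_val <= high, f"{name}: {true_val} outside [{low}, {high}]"
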