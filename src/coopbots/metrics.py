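"""Summary statistics and regression analyses over simulated sessions.

Works from in-memory :class:`SessionResult` objects or from the tidy CSVs
written by :mod:`coopbots.io`; both routes give identical numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .base import Action, DataError, NodeKind
from .engine import RoundRecord, SessionResult
from .network import Network


def cooperation_fraction(record: RoundRecord, humans: Sequence[int]) -> float:
    """Fraction of humans cooperating this round (bots excluded entirely)."""
    if len(humans) == 0:
        raise DataError("cooperation fraction undefined with zero humans")
    n_coop = sum(1 for h in humans if record.actions[h] == Action.C)
    return n_coop / len(humans)


def clustering_indices(
    net: Network, actions: Mapping[int, Action]
) -> tuple[float, float]:
    """Two cooperator-clustering measures on the human-human subgraph.

    Returns ``(cc_tie_fraction, strategy_assortativity)``:

    * the fraction of human-human ties joining two cooperators;
    * the attribute assortativity coefficient of the binary action.

    Undefined cases (no human ties; all humans playing the same action)
    come back as NaN, never as a silent zero.
    """
    humans = net.humans
    sub = net.g.subgraph(humans)
    n_edges = sub.number_of_edges()
    if n_edges == 0:
        cc_frac = math.nan
    else:
        cc = sum(
            1 for a, b in sub.edges() if actions[a] == Action.C and actions[b] == Action.C
        )
        cc_frac = cc / n_edges
    distinct = {actions[h] for h in humans}
    if n_edges == 0 or len(distinct) < 2:
        assort = math.nan
    else:
        g = nx.Graph(sub)
        nx.set_node_attributes(g, {h: actions[h].value for h in humans}, "action")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                assort = float(nx.attribute_assortativity_coefficient(g, "action"))
        except ZeroDivisionError:
            assort = math.nan
        if not math.isfinite(assort):
            assort = math.nan
    return cc_frac, assort


def earnings_by_behavior(result: SessionResult) -> pd.DataFrame:
    """Per-round mean cumulative earnings of current cooperators vs defectors.

    Humans are re-partitioned each round by that round's action; an empty
    group yields NaN for that round.
    """
    rows = []
    for rec in result.rounds:
        coop = [rec.cum_earnings[h] for h in result.humans if rec.actions[h] == Action.C]
        defe = [rec.cum_earnings[h] for h in result.humans if rec.actions[h] == Action.D]
        rows.append(
            {
                "round": rec.round,
                "mean_earnings_cooperators": float(np.mean(coop)) if coop else math.nan,
                "mean_earnings_defectors": float(np.mean(defe)) if defe else math.nan,
            }
        )
    return pd.DataFrame(rows)


def condition_summary(results: Iterable[SessionResult]) -> pd.DataFrame:
    """Per-round means (across sessions) of the headline series.

    Columns: condition, round, mean/sd cooperation fraction, mean human
    degree (bot ties included: the subject counts neighbors, not kinds),
    mean cooperator-clustering indices, and mean cumulative earnings split
    by current action.
    """
    rows = []
    for res in results:
        net = Network()
        for h in res.humans:
            net.add_node(h, NodeKind.HUMAN)
        for b in res.bots:
            net.add_node(b, NodeKind.BOT)
        for rec in res.rounds:
            net.g.remove_edges_from(list(net.g.edges()))
            net.g.add_edges_from(rec.edge_list)
            cc_frac, assort = clustering_indices(net, rec.actions)
            coop = [rec.cum_earnings[h] for h in res.humans if rec.actions[h] == Action.C]
            defe = [rec.cum_earnings[h] for h in res.humans if rec.actions[h] == Action.D]
            rows.append(
                {
                    "condition": res.config.condition.value,
                    "seed": res.config.seed,
                    "round": rec.round,
                    "coop_fraction": cooperation_fraction(rec, res.humans),
                    "mean_human_degree": float(
                        np.mean([net.degree(h) for h in res.humans])
                    ),
                    "cc_tie_fraction": cc_frac,
                    "strategy_assortativity": assort,
                    "mean_earnings_cooperators": float(np.mean(coop)) if coop else math.nan,
                    "mean_earnings_defectors": float(np.mean(defe)) if defe else math.nan,
                }
            )
    per_session = pd.DataFrame(rows)
    out = (
        per_session.groupby(["condition", "round"], sort=True)
        .agg(
            n_sessions=("seed", "nunique"),
            mean_coop_fraction=("coop_fraction", "mean"),
            sd_coop_fraction=("coop_fraction", "std"),
            mean_human_degree=("mean_human_degree", "mean"),
            mean_cc_tie_fraction=("cc_tie_fraction", "mean"),
            mean_strategy_assortativity=("strategy_assortativity", "mean"),
            mean_earnings_cooperators=("mean_earnings_cooperators", "mean"),
            mean_earnings_defectors=("mean_earnings_defectors", "mean"),
        )
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------


def decisions_frame(results: Iterable[SessionResult]) -> pd.DataFrame:
    """Individual human decisions in tidy form, one row per human x round.

    Covariates are exactly what the agent saw at decision time: degree
    ``k``, cooperative neighbors ``c`` (previous round), own previous
    action, and the round index.
    """
    rows = []
    for res in results:
        cond = res.config.condition.value
        sid = res.config.seed
        prev: dict[int, Action] | None = None
        for rec in res.rounds:
            for h in res.humans:
                k, c = rec.decision_inputs[h]
                rows.append(
                    {
                        "session": sid,
                        "condition": cond,
                        "subject": h,
                        "round": rec.round,
                        "coop": int(rec.actions[h] == Action.C),
                        "prev_coop": int(prev[h] == Action.C) if prev else np.nan,
                        "k": k,
                        "c": c,
                    }
                )
            prev = rec.actions
    return pd.DataFrame(rows)


@dataclass
class TrendEstimate:
    condition: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    converged: bool


@dataclass
class TrendModelResult:
    estimates: dict[str, TrendEstimate]
    method: str
    n_obs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition": e.condition,
                    "round_slope": e.slope,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "converged": e.converged,
                }
                for e in self.estimates.values()
            ]
        )


def trend_model(data: pd.DataFrame) -> TrendModelResult:
    """Per-condition round slope of the individual cooperation choice.

    Logistic regression of ``coop`` on condition x round with
    cluster-robust (session-level) covariance standing in for session and
    subject random intercepts; the method used is recorded in the result.
    Non-convergence or separation yields a flagged NaN estimate for the
    affected condition rather than an exception.
    """
    conditions = sorted(data["condition"].unique())
    estimates: dict[str, TrendEstimate] = {}
    for cond in conditions:
        sub = data[data["condition"] == cond]
        if sub["round"].nunique() < 2 or sub["session"].nunique() < 2:
            raise DataError(
                f"condition {cond}: need >= 2 rounds and >= 2 sessions for a trend"
            )
        X = sm.add_constant(sub[["round"]].astype(float))
        try:
            model = sm.GLM(sub["coop"].to_numpy(), X, family=sm.families.Binomial())
            fit = model.fit(cov_type="cluster", cov_kwds={"groups": sub["session"].to_numpy()})
            slope = float(fit.params["round"])
            se = float(fit.bse["round"])
            ci = fit.conf_int().loc["round"]
            ok = math.isfinite(slope) and math.isfinite(se)
            estimates[cond] = TrendEstimate(
                condition=cond,
                slope=slope,
                se=se,
                ci_low=float(ci[0]),
                ci_high=float(ci[1]),
                converged=ok,
            )
        except Exception:
            estimates[cond] = TrendEstimate(cond, math.nan, math.nan, math.nan, math.nan, False)
    return TrendModelResult(
        estimates=estimates, method="logit_cluster_cr", n_obs=len(data)
    )


def fit_cooperation_model(decisions: pd.DataFrame, center_interaction: bool = True):
    """Fit the conditional-cooperation logit to round >= 2 decisions.

    The design matrix mirrors the generating rule: previous action, degree,
    cooperative neighbors, their product, and round.  With
    ``center_interaction`` the product column has its mean removed, which
    shifts only the intercept and leaves every slope on the generating
    scale.  Returns the fitted statsmodels results object.
    """
    sub = decisions[decisions["round"] >= 2].copy()
    if sub.empty:
        raise DataError("no round >= 2 decisions to fit")
    sub["kc"] = sub["k"] * sub["c"]
    if center_interaction:
        sub["kc"] = sub["kc"] - sub["kc"].mean()
    X = sm.add_constant(sub[["prev_coop", "k", "c", "kc", "round"]].astype(float))
    model = sm.GLM(sub["coop"].to_numpy(), X, family=sm.families.Binomial())
    return model.fit(cov_type="cluster", cov_kwds={"groups": sub["session"].to_numpy()})
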