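"""Tidy on-disk formats for sessions: round records, options, edges, usage.

All CSVs are plain pandas frames with stable column order so that repeated
runs with the same seed produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .base import NodeKind
from .engine import SessionResult
from .network import Network, neighborhood_summary

ROUNDS_COLUMNS = [
    "session_id",
    "condition",
    "seed",
    "round",
    "node_id",
    "kind",
    "action",
    "payoff",
    "cum_earnings",
    "degree",
    "coop_neighbors",
]

OPTIONS_COLUMNS = [
    "session_id",
    "round",
    "decider",
    "counterpart",
    "action_type",
    "source",
    "counterpart_last_action",
    "accepted",
]

EDGES_COLUMNS = ["session_id", "round", "node_a", "node_b"]

USAGE_COLUMNS = [
    "session_id",
    "round",
    "n_self_rewire",
    "n_disengage_options",
    "n_engage_options",
]


def rounds_frame(result: SessionResult, session_id: str = "s0") -> pd.DataFrame:
    """One row per node per round with that round's action and neighborhood.

    Degree and cooperative-neighbor count are measured on the
    post-rewiring network of the round, against the round's revealed
    actions (the state a subject would see on their screen at round end).
    """
    cond = result.config.condition.value
    seed = result.config.seed
    net = _skeleton(result)
    rows = []
    for rec in result.rounds:
        net.g.remove_edges_from(list(net.g.edges()))
        net.g.add_edges_from(rec.edge_list)
        for i in sorted(rec.actions):
            k, c = neighborhood_summary(net, rec.actions, i)
            rows.append(
                {
                    "session_id": session_id,
                    "condition": cond,
                    "seed": seed,
                    "round": rec.round,
                    "node_id": i,
                    "kind": net.kind(i).value,
                    "action": rec.actions[i].value,
                    "payoff": round(rec.payoffs[i], 10),
                    "cum_earnings": round(rec.cum_earnings[i], 10),
                    "degree": k,
                    "coop_neighbors": c,
                }
            )
    return pd.DataFrame(rows, columns=ROUNDS_COLUMNS)


def options_frame(result: SessionResult, session_id: str = "s0") -> pd.DataFrame:
    rows = []
    for rec in result.rounds:
        accepted = set(map(id, rec.options_accepted))
        for opt in rec.options_issued:
            rows.append(
                {
                    "session_id": session_id,
                    "round": rec.round,
                    "decider": opt.decider,
                    "counterpart": opt.counterpart,
                    "action_type": opt.action_type.value,
                    "source": opt.source.value,
                    "counterpart_last_action": opt.counterpart_last_action.value,
                    "accepted": int(id(opt) in accepted),
                }
            )
    return pd.DataFrame(rows, columns=OPTIONS_COLUMNS)


def edges_frame(result: SessionResult, session_id: str = "s0") -> pd.DataFrame:
    rows = [
        {"session_id": session_id, "round": rec.round, "node_a": a, "node_b": b}
        for rec in result.rounds
        for a, b in rec.edge_list
    ]
    return pd.DataFrame(rows, columns=EDGES_COLUMNS)


def strategy_usage_frame(result: SessionResult, session_id: str = "s0") -> pd.DataFrame:
    rows = [
        {
            "session_id": session_id,
            "round": rec.round,
            "n_self_rewire": rec.mixed_branch_counts[0],
            "n_disengage_options": rec.mixed_branch_counts[1],
            "n_engage_options": rec.mixed_branch_counts[2],
        }
        for rec in result.rounds
    ]
    return pd.DataFrame(rows, columns=USAGE_COLUMNS)


def write_session(result: SessionResult, out_dir: str | Path, session_id: str = "s0") -> dict:
    """Write the four tidy CSVs for one session; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in [
        ("rounds", rounds_frame(result, session_id)),
        ("options", options_frame(result, session_id)),
        ("edges", edges_frame(result, session_id)),
        ("strategy_usage", strategy_usage_frame(result, session_id)),
    ]:
        path = out / f"{session_id}_{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def write_graphml(result: SessionResult, path: str | Path, round_index: int = -1) -> None:
    """Final (or chosen) round's network as GraphML with a "kind" attribute."""
    rec = result.rounds[round_index]
    g = nx.Graph()
    for h in result.humans:
        g.add_node(h, kind=NodeKind.HUMAN.value)
    for b in result.bots:
        g.add_node(b, kind=NodeKind.BOT.value)
    g.add_edges_from(rec.edge_list)
    nx.write_graphml(g, str(path))


def _skeleton(result: SessionResult) -> Network:
    net = Network()
    for h in result.humans:
        net.add_node(h, NodeKind.HUMAN)
    for b in result.bots:
        net.add_node(b, NodeKind.BOT)
    return net
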