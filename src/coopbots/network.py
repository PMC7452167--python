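"""Typed dynamic network over humans and bots.

A thin wrapper around :class:`networkx.Graph` that enforces the structural
rules of the experiments: no self-ties, no bot-bot ties, fixed bot ids
appended after the humans.  Humans are ``0..n_humans-1``; in matched-bot
conditions bot ``n_humans + i`` starts tied to human ``i``; in the
single-bot condition one bot (id ``n_humans``) starts with 5 ties.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import numpy as np

from .base import (
    Action,
    Condition,
    ConfigurationError,
    DataError,
    MATCHED_BOT_CONDITIONS,
    NodeKind,
    OptionType,
    StructuralError,
)

_SYLLABLES = (
    "ba be bi bo bu da de di do du ka ke ki ko ku la le li lo lu "
    "ma me mi mo mu na ne ni no nu ra re ri ro ru sa se si so su "
    "ta te ti to tu va ve vi vo vu za ze zi zo zu"
).split()


def _pseudonym(rng: np.random.Generator) -> str:
    """A short pronounceable display name; purely cosmetic."""
    parts = rng.choice(len(_SYLLABLES), size=3)
    return "".join(_SYLLABLES[i] for i in parts).capitalize()


class Network:
    """Undirected graph over typed nodes with a mutable tie set."""

    def __init__(self, graph: nx.Graph | None = None):
        self.g = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: int, kind: NodeKind, label: str = "") -> None:
        if node_id in self.g:
            raise StructuralError(f"duplicate node id {node_id}")
        self.g.add_node(node_id, kind=kind, label=label or f"{kind.value[0]}{node_id}")

    # -- queries ----------------------------------------------------------

    def kind(self, node_id: int) -> NodeKind:
        return self.g.nodes[node_id]["kind"]

    @property
    def humans(self) -> list[int]:
        return sorted(i for i, d in self.g.nodes(data=True) if d["kind"] == NodeKind.HUMAN)

    @property
    def bots(self) -> list[int]:
        return sorted(i for i, d in self.g.nodes(data=True) if d["kind"] == NodeKind.BOT)

    def neighbors(self, node_id: int) -> list[int]:
        return sorted(self.g.neighbors(node_id))

    def degree(self, node_id: int) -> int:
        return self.g.degree[node_id]

    def has_tie(self, a: int, b: int) -> bool:
        return self.g.has_edge(a, b)

    def ties(self) -> list[tuple[int, int]]:
        """Sorted edge list with each pair ordered (low, high)."""
        return sorted((a, b) if a < b else (b, a) for a, b in self.g.edges())

    def human_pairs(self) -> list[tuple[int, int]]:
        """All unordered human-human pairs, tied or not, in sorted order."""
        hs = self.humans
        return [(hs[i], hs[j]) for i in range(len(hs)) for j in range(i + 1, len(hs))]

    def copy(self) -> "Network":
        return Network(self.g.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            set(self.g.nodes) == set(other.g.nodes)
            and {i: d["kind"] for i, d in self.g.nodes(data=True)}
            == {i: d["kind"] for i, d in other.g.nodes(data=True)}
            and self.ties() == other.ties()
        )


def init_er_network(n_humans: int, density: float, rng: np.random.Generator) -> Network:
    """Erdős–Rényi G(n, p) over humans only: each pair tied independently.

    The expected (not exact) tie count is ``density * C(n, 2)``, matching a
    design where "30% of the possible ties" holds on average.
    """
    if n_humans < 2:
        raise ConfigurationError(f"n_humans must be >= 2, got {n_humans}")
    if not 0.0 <= density <= 1.0:
        raise ConfigurationError(f"density must be in [0, 1], got {density}")
    net = Network()
    for i in range(n_humans):
        net.add_node(i, NodeKind.HUMAN, _pseudonym(rng))
    pairs = net.human_pairs()
    draws = rng.random(len(pairs))
    for (a, b), u in zip(pairs, draws):
        if u < density:
            net.g.add_edge(a, b)
    return net


def attach_bots(net: Network, condition: Condition, rng: np.random.Generator) -> Network:
    """Add the condition's bots to an all-human network (in place).

    Matched-bot conditions: one bot per human, bot ``n + i`` tied to human
    ``i`` (a perfect matching, so every human starts with exactly one bot
    neighbor).  SINGLE_MIXED: one bot tied to 5 distinct humans chosen
    uniformly at random.  NO_BOT: returned unchanged.
    """
    if net.bots:
        raise StructuralError("attach_bots requires an all-human network")
    if condition == Condition.NO_BOT:
        return net
    humans = net.humans
    n = len(humans)
    if condition in MATCHED_BOT_CONDITIONS:
        for i, h in enumerate(humans):
            bot = n + i
            net.add_node(bot, NodeKind.BOT, _pseudonym(rng))
            net.g.add_edge(h, bot)
        return net
    if condition == Condition.SINGLE_MIXED:
        n_ties = min(5, n)
        bot = n
        net.add_node(bot, NodeKind.BOT, _pseudonym(rng))
        chosen = rng.choice(humans, size=n_ties, replace=False)
        for h in sorted(int(h) for h in chosen):
            net.g.add_edge(h, bot)
        return net
    raise ConfigurationError(f"unknown condition: {condition!r}")


def rewire(net: Network, make_or_break: OptionType, a: int, b: int) -> Network:
    """Apply a single tie mutation in place, enforcing all invariants."""
    if a == b:
        raise StructuralError(f"self-tie forbidden: ({a}, {b})")
    for node in (a, b):
        if node not in net.g:
            raise StructuralError(f"unknown node {node} in pair ({a}, {b})")
    if make_or_break == OptionType.MAKE:
        if net.kind(a) == NodeKind.BOT and net.kind(b) == NodeKind.BOT:
            raise StructuralError(f"bot-bot tie forbidden: ({a}, {b})")
        if net.has_tie(a, b):
            raise StructuralError(f"MAKE on existing tie ({a}, {b})")
        net.g.add_edge(a, b)
    elif make_or_break == OptionType.BREAK:
        if not net.has_tie(a, b):
            raise StructuralError(f"BREAK on absent tie ({a}, {b})")
        net.g.remove_edge(a, b)
    else:
        raise ConfigurationError(f"unknown rewiring type: {make_or_break!r}")
    return net


def neighborhood_summary(
    net: Network, actions: Mapping[int, Action], i: int
) -> tuple[int, int]:
    """(degree, number of cooperating neighbors) of node ``i``.

    Bots count as neighbors like anyone else: subjects could not
    distinguish them.
    """
    k = 0
    c = 0
    for j in net.g.neighbors(i):
        k += 1
        try:
            a = actions[j]
        except KeyError:
            raise DataError(f"no action recorded for neighbor {j} of node {i}") from None
        if a == Action.C:
            c += 1
    return k, c


def check_invariants(net: Network, condition: Condition | None = None) -> None:
    """Raise StructuralError if any structural rule is violated.

    With a condition given, also checks the per-condition bot-degree rules
    (matched bots keep exactly one tie; the single mixed bot never exceeds
    5 ties).
    """
    for a, b in net.g.edges():
        if a == b:
            raise StructuralError(f"self-tie ({a}, {b})")
        if net.kind(a) == NodeKind.BOT and net.kind(b) == NodeKind.BOT:
            raise StructuralError(f"bot-bot tie ({a}, {b})")
    if condition in MATCHED_BOT_CONDITIONS:
        for bot in net.bots:
            if net.degree(bot) != 1:
                raise StructuralError(f"matched bot {bot} has degree {net.degree(bot)} != 1")
    elif condition == Condition.SINGLE_MIXED:
        (bot,) = net.bots
        if net.degree(bot) > 5:
            raise StructuralError(f"single bot degree {net.degree(bot)} exceeds 5")
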