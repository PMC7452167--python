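"""Per-round game cycle and full-session execution.

Each round runs in a fixed phase order:

1. simultaneous decisions — humans via the behavioral model, bots via
   their policy, both using only the previous round's revealed actions;
2. public-goods payoffs applied to cumulative earnings;
3. revelation of this round's actions;
4. single mixed bot self-rewiring (single-bot condition, rounds >= 2);
5. rewiring lottery over human pairs;
6. bot intervention options (intervention conditions);
7. option resolution — every option is accepted or rejected independently
   by its decider, then accepted options are applied in issuance order,
   skipping any whose precondition an earlier application destroyed.

Everything is driven by one seeded generator, so a session is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .base import (
    Action,
    Condition,
    INTERVENTION_CONDITIONS,
    OptionSource,
    OptionType,
    RewiringOption,
    StructuralError,
)
from .bots import (
    MixedStepRecord,
    bot_action,
    generate_intervention,
    policy_for_condition,
    single_mixed_step,
)
from .config import SessionConfig
from .humans import decide_cooperation, decide_rewiring
from .network import (
    Network,
    attach_bots,
    check_invariants,
    init_er_network,
    neighborhood_summary,
    rewire,
)


@dataclass
class RoundRecord:
    """Everything that happened in one round, in decision order."""

    round: int
    actions: dict[int, Action]
    payoffs: dict[int, float]
    cum_earnings: dict[int, float]
    decision_inputs: dict[int, tuple[int, int]]  # human -> (k, c) at decision time
    options_issued: list[RewiringOption]
    options_accepted: list[RewiringOption]
    options_applied: list[RewiringOption]
    bot_self_rewires: list[tuple[tuple[int, int] | None, tuple[int, int] | None]]
    mixed_branch_counts: tuple[int, int, int]  # (self-rewires, disengage, engage)
    edge_list: tuple[tuple[int, int], ...]  # tie snapshot after rewiring


@dataclass
class SessionResult:
    config: SessionConfig
    humans: tuple[int, ...]
    bots: tuple[int, ...]
    initial_edge_list: tuple[tuple[int, int], ...]  # ties before round 1
    rounds: list[RoundRecord]
    final_earnings: dict[int, float]
    final_network: Network


@dataclass
class SessionState:
    """Mutable state threaded through play_round."""

    net: Network
    cfg: SessionConfig
    round: int = 1
    prev_actions: dict[int, Action] | None = None
    cum_earnings: dict[int, float] = field(default_factory=dict)


def compute_payoffs(
    net: Network, actions: Mapping[int, Action], cfg: SessionConfig
) -> dict[int, float]:
    """Round payoff delta per node.

    A cooperator pays ``cost * degree`` and every node receives ``benefit``
    per cooperating neighbor; bots are scored too, purely as bookkeeping.
    """
    payoffs: dict[int, float] = {}
    for i in sorted(net.g.nodes):
        try:
            own = actions[i]
        except KeyError:
            raise StructuralError(f"no action for node {i}") from None
        k, c = neighborhood_summary(net, actions, i)
        delta = cfg.benefit_to_each_neighbor * c
        if own == Action.C:
            delta -= cfg.coop_cost_per_neighbor * k
        payoffs[i] = delta
    return payoffs


def draw_lottery(
    net: Network,
    rate: float,
    rng: np.random.Generator,
    last_actions: Mapping[int, Action],
) -> list[RewiringOption]:
    """Independent per-pair rewiring lottery over human pairs only.

    Each unordered human pair enters with probability ``rate``; a tied pair
    yields a BREAK offer, an untied pair a MAKE offer, with the decider
    picked uniformly from the two.
    """
    options: list[RewiringOption] = []
    pairs = net.human_pairs()
    draws = rng.random(len(pairs))
    for (a, b), u in zip(pairs, draws):
        if u >= rate:
            continue
        action_type = OptionType.BREAK if net.has_tie(a, b) else OptionType.MAKE
        decider, counterpart = (a, b) if rng.random() < 0.5 else (b, a)
        options.append(
            RewiringOption(
                decider=decider,
                counterpart=counterpart,
                action_type=action_type,
                source=OptionSource.LOTTERY,
                counterpart_last_action=last_actions[counterpart],
            )
        )
    return options


def _option_valid(net: Network, opt: RewiringOption) -> bool:
    tied = net.has_tie(opt.decider, opt.counterpart)
    return tied if opt.action_type == OptionType.BREAK else not tied


def play_round(state: SessionState, rng: np.random.Generator) -> RoundRecord:
    cfg = state.cfg
    net = state.net
    t = state.round
    params = cfg.human_params

    # Phase 1: simultaneous decisions from round-(t-1) information.
    actions: dict[int, Action] = {}
    decision_inputs: dict[int, tuple[int, int]] = {}
    for h in net.humans:
        if t == 1 or state.prev_actions is None:
            k, c = net.degree(h), 0
            prev = None
        else:
            k, c = neighborhood_summary(net, state.prev_actions, h)
            prev = state.prev_actions[h]
        decision_inputs[h] = (k, c)
        actions[h] = decide_cooperation(params, k, c, prev, t, rng)
    if cfg.condition != Condition.NO_BOT:
        policy = policy_for_condition(cfg.condition)
        for b in net.bots:
            actions[b] = bot_action(policy, b, net, state.prev_actions, t)

    # Phase 2: payoffs accumulate.
    payoffs = compute_payoffs(net, actions, cfg)
    for i, delta in payoffs.items():
        state.cum_earnings[i] = state.cum_earnings.get(i, cfg.endowment) + delta

    # Phase 3: this round's actions are now public knowledge.
    last_actions = actions

    # Phase 4: single mixed bot self-rewiring (needs a completed prior round).
    mixed: MixedStepRecord | None = None
    if cfg.condition == Condition.SINGLE_MIXED and t >= 2:
        (bot,) = net.bots
        mixed = single_mixed_step(bot, net, last_actions, rng)

    # Phase 5: rewiring lottery over human pairs.
    options = draw_lottery(net, cfg.lottery_rate, rng, last_actions)

    # Phase 6: bot-sourced options (after lottery in the issuance order).
    if cfg.condition in INTERVENTION_CONDITIONS:
        policy = policy_for_condition(cfg.condition)
        for b in net.bots:
            opt = generate_intervention(policy, b, net, last_actions, rng)
            if opt is not None:
                options.append(opt)
    elif mixed is not None:
        options.extend(mixed.options)

    # Phase 7: independent acceptance, then sequential application with skip.
    accepted = [opt for opt in options if decide_rewiring(params, opt, rng)]
    applied: list[RewiringOption] = []
    for opt in accepted:
        if not _option_valid(net, opt):
            continue  # invalidated by an earlier application this round
        rewire(net, opt.action_type, opt.decider, opt.counterpart)
        applied.append(opt)

    check_invariants(net, cfg.condition)

    return RoundRecord(
        round=t,
        actions=actions,
        payoffs=payoffs,
        cum_earnings=dict(state.cum_earnings),
        decision_inputs=decision_inputs,
        options_issued=options,
        options_accepted=accepted,
        options_applied=applied,
        bot_self_rewires=mixed.self_rewires if mixed else [],
        mixed_branch_counts=(
            (mixed.n_self_rewire, mixed.n_disengage_options, mixed.n_engage_options)
            if mixed
            else (0, 0, 0)
        ),
        edge_list=tuple(net.ties()),
    )


def build_initial_network(cfg: SessionConfig, rng: np.random.Generator) -> Network:
    net = init_er_network(cfg.n_humans, cfg.initial_density, rng)
    attach_bots(net, cfg.condition, rng)
    check_invariants(net, cfg.condition)
    return net


def run_session(cfg: SessionConfig) -> SessionResult:
    """Execute one full session; deterministic given (config, seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    net = build_initial_network(cfg, rng)
    initial_edge_list = tuple(net.ties())
    state = SessionState(
        net=net,
        cfg=cfg,
        cum_earnings={i: cfg.endowment for i in sorted(net.g.nodes)},
    )
    rounds: list[RoundRecord] = []
    for t in range(1, cfg.n_rounds + 1):
        state.round = t
        try:
            record = play_round(state, rng)
        except StructuralError as exc:
            raise StructuralError(f"round {t}: {exc}") from exc
        rounds.append(record)
        state.prev_actions = record.actions
    return SessionResult(
        config=cfg,
        humans=tuple(net.humans),
        bots=tuple(net.bots),
        initial_edge_list=initial_edge_list,
        rounds=rounds,
        final_earnings=dict(state.cum_earnings),
        final_network=net,
    )
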