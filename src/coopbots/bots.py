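"""Bot policies: game actions, network-intervention options, and the
single-bot mixed strategy.

All bots cooperate unconditionally except the tit-for-tat control, which
copies its single human neighbor's previous action.  Intervention bots do
not play strategically at all — their lever is the extra rewiring option
they hand to their human neighbor each round:

* random      — make/break with a uniformly chosen other human;
* engaged     — make a tie to a current cooperator (conciliatory);
* disengaged  — break a tie to a currently defecting neighbor (quarantine).

The Experiment-2 single bot mixes these: it rewires *itself* away from
neighbors who defected, offers disengagement to cooperating neighbors with
defector contacts, and offers engagement once a neighbor's whole
neighborhood cooperates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .base import (
    Action,
    Condition,
    ConfigurationError,
    NodeKind,
    OptionSource,
    OptionType,
    RewiringOption,
    StructuralError,
)
from .network import Network, rewire


class BotPolicy(str, enum.Enum):
    ALWAYS_C = "always_c"
    TFT = "tft"
    RANDOM_INT = "random"
    ENGAGED_INT = "engaged"
    DISENGAGED_INT = "disengaged"
    SINGLE_MIXED = "single_mixed"


_CONDITION_POLICY = {
    Condition.ALWAYS_COOPERATE: BotPolicy.ALWAYS_C,
    Condition.TFT: BotPolicy.TFT,
    Condition.RANDOM_INT: BotPolicy.RANDOM_INT,
    Condition.ENGAGED_INT: BotPolicy.ENGAGED_INT,
    Condition.DISENGAGED_INT: BotPolicy.DISENGAGED_INT,
    Condition.DISENGAGED_VISIBLE: BotPolicy.DISENGAGED_INT,
    Condition.SINGLE_MIXED: BotPolicy.SINGLE_MIXED,
}

_INTERVENTION_POLICIES = frozenset(
    {BotPolicy.RANDOM_INT, BotPolicy.ENGAGED_INT, BotPolicy.DISENGAGED_INT}
)


def policy_for_condition(condition: Condition) -> BotPolicy:
    try:
        return _CONDITION_POLICY[condition]
    except KeyError:
        raise ConfigurationError(f"condition {condition!r} has no bots") from None


def bot_action(
    policy: BotPolicy,
    bot: int,
    net: Network,
    prev_actions: Mapping[int, Action] | None,
    round_index: int,
) -> Action:
    """The bot's game choice for this round.

    Only TFT can defect: it starts with cooperation and then mirrors its
    single neighbor's previous action.
    """
    if policy != BotPolicy.TFT:
        return Action.C
    neighbors = net.neighbors(bot)
    if len(neighbors) != 1:
        raise StructuralError(f"TFT bot {bot} must have exactly one neighbor, has {len(neighbors)}")
    if round_index == 1 or prev_actions is None:
        return Action.C
    return prev_actions[neighbors[0]]


def generate_intervention(
    policy: BotPolicy,
    bot: int,
    net: Network,
    prev_actions: Mapping[int, Action],
    rng: np.random.Generator,
) -> RewiringOption | None:
    """One rewiring option from a matched (single-tie) intervention bot.

    The option goes to the bot's human neighbor ``h`` regardless of h's
    own last action; an empty eligible set yields no option that round.
    """
    if policy not in _INTERVENTION_POLICIES:
        raise ConfigurationError(f"{policy} is not an intervention policy")
    neighbors = [j for j in net.neighbors(bot) if net.kind(j) == NodeKind.HUMAN]
    if len(neighbors) != 1:
        raise StructuralError(
            f"intervention bot {bot} must have exactly one human neighbor, has {len(neighbors)}"
        )
    h = neighbors[0]
    humans = net.humans

    if policy == BotPolicy.RANDOM_INT:
        candidates = [j for j in humans if j != h]
        if not candidates:
            return None
        j = int(rng.choice(candidates))
        action_type = OptionType.BREAK if net.has_tie(h, j) else OptionType.MAKE
    elif policy == BotPolicy.ENGAGED_INT:
        candidates = [
            j
            for j in humans
            if j != h and prev_actions.get(j) == Action.C and not net.has_tie(h, j)
        ]
        if not candidates:
            return None
        j = int(rng.choice(candidates))
        action_type = OptionType.MAKE
    else:  # DISENGAGED_INT
        candidates = [
            j
            for j in net.neighbors(h)
            if net.kind(j) == NodeKind.HUMAN and prev_actions.get(j) == Action.D
        ]
        if not candidates:
            return None
        j = int(rng.choice(candidates))
        action_type = OptionType.BREAK

    return RewiringOption(
        decider=h,
        counterpart=j,
        action_type=action_type,
        source=OptionSource.BOT,
        counterpart_last_action=prev_actions[j],
    )


@dataclass
class MixedStepRecord:
    """What the single mixed-strategy bot did in one rewiring phase."""

    self_rewires: list[tuple[tuple[int, int] | None, tuple[int, int] | None]] = field(
        default_factory=list
    )
    options: list[RewiringOption] = field(default_factory=list)
    n_self_rewire: int = 0
    n_disengage_options: int = 0
    n_engage_options: int = 0


def single_mixed_step(
    bot: int,
    net: Network,
    prev_actions: Mapping[int, Action],
    rng: np.random.Generator,
) -> MixedStepRecord:
    """One pass of the Experiment-2 mixed strategy (mutates ``net``).

    For each of the bot's current neighbors ``h`` exactly one branch fires:

    (a) ``h`` defected last round — the bot detaches from ``h`` and attaches
        to a uniformly chosen last-round cooperator it is not already tied
        to (a "self-rewire"; if no such cooperator exists the tie is kept,
        so the bot never dangles);
    (b) ``h`` cooperated but has at least one defecting neighbor — the bot
        offers ``h`` a break with one such neighbor, chosen uniformly;
    (c) ``h`` cooperated and the whole neighborhood cooperated — the bot
        offers ``h`` a new tie to a uniformly chosen untied cooperator, or
        nothing if none exists.

    Self-rewires are applied before the (b)/(c) options are generated, so
    options reference the post-self-rewire network.
    """
    record = MixedStepRecord()
    original_neighbors = net.neighbors(bot)

    # Branch (a): first, detach from defectors and reattach to cooperators.
    cooperating_partners: list[int] = []
    for h in original_neighbors:
        if prev_actions[h] == Action.D:
            candidates = [
                j
                for j in net.humans
                if prev_actions.get(j) == Action.C and not net.has_tie(bot, j)
            ]
            if candidates:
                j = int(rng.choice(candidates))
                rewire(net, OptionType.BREAK, bot, h)
                rewire(net, OptionType.MAKE, bot, j)
                record.self_rewires.append(((bot, h), (bot, j)))
                record.n_self_rewire += 1
            else:
                # Nobody to move to: keep the tie so degree is preserved.
                record.self_rewires.append(((bot, h), None))
        else:
            cooperating_partners.append(h)

    # Branches (b)/(c) for the neighbors that cooperated.
    for h in cooperating_partners:
        h_neighbors = [j for j in net.neighbors(h) if j != bot]
        defectors = [j for j in h_neighbors if prev_actions.get(j) == Action.D]
        if defectors:
            j = int(rng.choice(defectors))
            record.options.append(
                RewiringOption(
                    decider=h,
                    counterpart=j,
                    action_type=OptionType.BREAK,
                    source=OptionSource.BOT,
                    counterpart_last_action=prev_actions[j],
                )
            )
            record.n_disengage_options += 1
        else:
            candidates = [
                j
                for j in net.humans
                if j != h and prev_actions.get(j) == Action.C and not net.has_tie(h, j)
            ]
            if candidates:
                j = int(rng.choice(candidates))
                record.options.append(
                    RewiringOption(
                        decider=h,
                        counterpart=j,
                        action_type=OptionType.MAKE,
                        source=OptionSource.BOT,
                        counterpart_last_action=prev_actions[j],
                    )
                )
                record.n_engage_options += 1
    return record
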