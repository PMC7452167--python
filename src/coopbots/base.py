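"""Shared vocabulary: node kinds, actions, experimental conditions, rewiring options.

Every other module builds on these types.  Node identifiers are plain
integers; humans occupy ``0..n_humans-1`` and bots are appended after them,
so id ordering is also a deterministic iteration order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class ConfigurationError(ValueError):
    """A config value is out of range or a condition/policy is unknown."""


class StructuralError(ValueError):
    """A network mutation would violate a structural invariant."""


class DataError(ValueError):
    """Required per-node data (e.g. an action) is missing or inconsistent."""


class NodeKind(str, enum.Enum):
    HUMAN = "human"
    BOT = "bot"


class Action(str, enum.Enum):
    C = "C"  # cooperate: pay $0.05 per neighbor, each neighbor gains $0.10
    D = "D"  # defect: pay nothing, give nothing


class Condition(str, enum.Enum):
    """Experimental condition: which bots (if any) are embedded in the group."""

    NO_BOT = "no_bot"
    ALWAYS_COOPERATE = "always_cooperate"
    TFT = "tft"
    RANDOM_INT = "random"
    ENGAGED_INT = "engaged"
    DISENGAGED_INT = "disengaged"
    DISENGAGED_VISIBLE = "disengaged_visible"
    SINGLE_MIXED = "single_mixed"


#: Conditions with one single-tie bot per human (the matched-bot design).
MATCHED_BOT_CONDITIONS = frozenset(
    {
        Condition.ALWAYS_COOPERATE,
        Condition.TFT,
        Condition.RANDOM_INT,
        Condition.ENGAGED_INT,
        Condition.DISENGAGED_INT,
        Condition.DISENGAGED_VISIBLE,
    }
)

#: Matched-bot conditions whose bots issue rewiring options to their neighbor.
INTERVENTION_CONDITIONS = frozenset(
    {
        Condition.RANDOM_INT,
        Condition.ENGAGED_INT,
        Condition.DISENGAGED_INT,
        Condition.DISENGAGED_VISIBLE,
    }
)

#: The six conditions of the first experiment (the regression set).
EXPERIMENT1_CONDITIONS = (
    Condition.NO_BOT,
    Condition.ALWAYS_COOPERATE,
    Condition.TFT,
    Condition.RANDOM_INT,
    Condition.ENGAGED_INT,
    Condition.DISENGAGED_INT,
)


class OptionType(str, enum.Enum):
    MAKE = "make"
    BREAK = "break"


class OptionSource(str, enum.Enum):
    LOTTERY = "lottery"
    BOT = "bot"


@dataclass(frozen=True)
class RewiringOption:
    """A unilateral make/break offer shown to one human.

    The decider sees only the counterpart's most recent revealed action;
    acceptance is resolved by the human model.
    """

    decider: int
    counterpart: int
    action_type: OptionType
    source: OptionSource
    counterpart_last_action: Action

    def __post_init__(self) -> None:
        if self.decider == self.counterpart:
            raise StructuralError("rewiring option cannot target the decider itself")

    @property
    def pair(self) -> tuple[int, int]:
        a, b = self.decider, self.counterpart
        return (a, b) if a < b else (b, a)
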