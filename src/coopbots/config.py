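"""Session configuration and human behavioral parameters.

Both dataclasses round-trip to plain dicts and to YAML/JSON config files,
field for field.  Defaults encode the published experimental design:
16 humans, 30 rounds, 30% initial density, a 5% rewiring lottery, and the
$1.00 / $0.05 / $0.10 payoff constants of the public-goods game.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .base import Action, Condition, ConfigurationError, OptionSource, OptionType, RewiringOption


@dataclass
class HumanModelParams:
    """Parameters of the stochastic human stand-in.

    The cooperation decision is a logistic ("conditional cooperation")
    rule: at round 1 humans cooperate with probability ``p0``; afterwards

        P(C) = logistic(b_intercept + b_prev*[prev=C] + b_degree*k
                        + b_coop*c + b_inter*k*c + b_round*t)

    where ``k`` is the current number of neighbors and ``c`` the number of
    them who cooperated in the previous round.  ``b_degree`` is negative
    and ``b_coop`` positive, so cooperating neighbors encourage and sheer
    degree discourages cooperation; the product term lets the *fraction*
    of cooperative neighbors matter beyond the raw count.

    Rewiring offers are accepted with probabilities conditioned on the
    offer type and the counterpart's last revealed action; defaults favor
    breaking with defectors and linking with cooperators.
    ``bot_source_mult`` scales the acceptance *odds* of bot-sourced offers
    (1.0 = humans treat bot suggestions like lottery draws, matching the
    observed null effect of bot visibility).

    Defaults are the shipped calibration.  The structure sets
    ``b_coop`` slightly below ``|b_degree|``, so gaining or losing a
    *cooperating* neighbor is nearly neutral (the probability contours run
    almost parallel to that move) while gaining or losing a *defecting*
    neighbor shifts the logit by the full ``b_degree``; group dynamics are
    then driven by defector ties.  Given that structure, ``p0`` and
    (``b_intercept``, ``b_round``) were fitted against the no-bot control
    trajectory only (68.2% initial cooperation decaying to 36.4% by round
    30, 200 sessions per evaluation); see :func:`coopbots.humans.calibrate`.
    The fitted round drift is ~0: the decay of unassisted groups emerges
    from defectors degrading their neighbors' environments, not from a
    secular time trend.
    """

    p0: float = 0.682
    b_intercept: float = 0.400
    b_prev: float = 1.5
    b_degree: float = -0.42
    b_coop: float = 0.50
    b_inter: float = 0.0
    b_round: float = 0.001
    p_break_d: float = 0.7
    p_break_c: float = 0.1
    p_make_c: float = 0.9
    p_make_d: float = 0.3
    bot_source_mult: float = 1.0

    def validate(self) -> None:
        probs = {
            "p0": self.p0,
            "p_break_d": self.p_break_d,
            "p_break_c": self.p_break_c,
            "p_make_c": self.p_make_c,
            "p_make_d": self.p_make_d,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"human_params.{name} must be in [0, 1], got {p}")
        if self.bot_source_mult < 0:
            raise ConfigurationError("human_params.bot_source_mult must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HumanModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown human_params fields: {sorted(unknown)}")
        params = cls(**d)
        params.validate()
        return params


@dataclass
class SessionConfig:
    """Full configuration of one 30-round session."""

    n_humans: int = 16
    n_rounds: int = 30
    initial_density: float = 0.30
    lottery_rate: float = 0.05
    endowment: float = 1.00
    coop_cost_per_neighbor: float = 0.05
    benefit_to_each_neighbor: float = 0.10
    condition: Condition = Condition.NO_BOT
    human_params: HumanModelParams = field(default_factory=HumanModelParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_humans < 2:
            raise ConfigurationError(f"n_humans must be >= 2, got {self.n_humans}")
        if self.n_rounds < 1:
            raise ConfigurationError(f"n_rounds must be >= 1, got {self.n_rounds}")
        for name in ("initial_density", "lottery_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("endowment", "coop_cost_per_neighbor", "benefit_to_each_neighbor"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not isinstance(self.condition, Condition):
            raise ConfigurationError(f"unknown condition: {self.condition!r}")
        self.human_params.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["condition"] = self.condition.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        if "condition" in d and not isinstance(d["condition"], Condition):
            try:
                d["condition"] = Condition(d["condition"])
            except ValueError as exc:
                raise ConfigurationError(f"unknown condition: {d['condition']!r}") from exc
        if "human_params" in d and isinstance(d["human_params"], dict):
            d["human_params"] = HumanModelParams.from_dict(d["human_params"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> SessionConfig:
    """Read a SessionConfig from a YAML or JSON file (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    return SessionConfig.from_dict(data)


def save_config(cfg: SessionConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


__all__ = [
    "Action",
    "Condition",
    "ConfigurationError",
    "HumanModelParams",
    "OptionSource",
    "OptionType",
    "RewiringOption",
    "SessionConfig",
    "load_config",
    "save_config",
]
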