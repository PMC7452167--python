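"""Experiment orchestration: many independently seeded sessions per condition.

Session seeds are spawned deterministically from one master seed, so the
whole experiment — and any single session rerun on its own — is exactly
reproducible.  Bundled designs make the published session arithmetic
executable: ``paper_full`` is 8 conditions x 8 sessions (64 groups, 1,024
simulated subjects), ``exp1_six`` the six-condition regression set (48
sessions, 768 subjects), and ``exp2_single`` the 8 single-bot sessions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .base import Condition, ConfigurationError, EXPERIMENT1_CONDITIONS
from .config import SessionConfig
from .engine import SessionResult, run_session
from . import io as session_io
from .metrics import condition_summary

__version__ = "0.1.0"


@dataclass
class ExperimentDesign:
    name: str
    arms: list[tuple[Condition, int]]  # (condition, n_sessions)
    template: SessionConfig = field(default_factory=SessionConfig)
    master_seed: int = 0

    def validate(self) -> None:
        if not self.arms:
            raise ConfigurationError("experiment design has no arms")
        for cond, n in self.arms:
            if not isinstance(cond, Condition):
                raise ConfigurationError(f"unknown condition {cond!r}")
            if n < 1:
                raise ConfigurationError(f"n_sessions must be >= 1 for {cond.value}")
        self.template.validate()

    @property
    def n_sessions(self) -> int:
        return sum(n for _, n in self.arms)

    @property
    def n_subjects(self) -> int:
        return self.n_sessions * self.template.n_humans


def bundled_design(name: str, master_seed: int = 0, template: SessionConfig | None = None) -> ExperimentDesign:
    """One of the shipped designs: paper_full | exp1_six | exp2_single."""
    template = template if template is not None else SessionConfig()
    if name == "paper_full":
        arms = [(c, 8) for c in Condition]
    elif name == "exp1_six":
        arms = [(c, 8) for c in EXPERIMENT1_CONDITIONS]
    elif name == "exp2_single":
        arms = [(Condition.SINGLE_MIXED, 8)]
    else:
        raise ConfigurationError(f"unknown bundled design: {name!r}")
    return ExperimentDesign(name=name, arms=arms, template=template, master_seed=master_seed)


def session_configs(design: ExperimentDesign) -> list[SessionConfig]:
    """Expand a design into per-session configs with spawned seeds.

    Seeds come from one SeedSequence over the master seed, in arm order,
    so session i is reproducible in isolation.
    """
    design.validate()
    seeds = np.random.SeedSequence(design.master_seed).generate_state(design.n_sessions)
    seeds = (seeds & 0x7FFFFFFF).tolist()
    configs = []
    idx = 0
    for cond, n in design.arms:
        for _ in range(n):
            configs.append(replace(design.template, condition=cond, seed=int(seeds[idx])))
            idx += 1
    return configs


def config_hash(design: ExperimentDesign) -> str:
    payload = {
        "name": design.name,
        "arms": [(c.value, n) for c, n in design.arms],
        "template": design.template.to_dict(),
        "master_seed": design.master_seed,
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class ExperimentResult:
    design: ExperimentDesign
    results: list[SessionResult]
    manifest: dict
    summary: pd.DataFrame
    failures: list[dict]


def run_experiment(
    design: ExperimentDesign, out_dir: str | Path | None = None, write_sessions: bool = True
) -> ExperimentResult:
    """Run every session of the design; optionally write the result bundle.

    Per-session failures are logged into the manifest (condition marked
    incomplete) instead of aborting the remaining sessions.
    """
    configs = session_configs(design)
    results: list[SessionResult] = []
    failures: list[dict] = []
    session_rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for i, cfg in enumerate(configs):
        session_id = f"{cfg.condition.value}_{i:03d}"
        try:
            result = run_session(cfg)
        except Exception as exc:  # session-level isolation
            failures.append(
                {"session_id": session_id, "condition": cfg.condition.value, "error": str(exc)}
            )
            continue
        results.append(result)
        session_rows.append(
            {
                "session_id": session_id,
                "condition": cfg.condition.value,
                "seed": cfg.seed,
                "n_humans": cfg.n_humans,
                "n_bots": len(result.bots),
                "n_rounds": cfg.n_rounds,
            }
        )
        if out is not None and write_sessions:
            session_io.write_session(result, out / "sessions", session_id)

    summary = condition_summary(results) if results else pd.DataFrame()
    incomplete = sorted({f["condition"] for f in failures})
    manifest = {
        "design": design.name,
        "version": __version__,
        "master_seed": design.master_seed,
        "config_hash": config_hash(design),
        "n_sessions": len(results),
        "n_subjects": sum(len(r.humans) for r in results),
        "sessions": session_rows,
        "failures": failures,
        "incomplete_conditions": incomplete,
    }
    if out is not None:
        summary.to_csv(out / "condition_summary.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return ExperimentResult(
        design=design, results=results, manifest=manifest, summary=summary, failures=failures
    )
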