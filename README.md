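# coopbots

Agent-based simulation of **bot-assisted partner selection in networked
public-goods games**.

Groups of 16 people playing a repeated public-goods game on a social
network usually see cooperation decay: defectors exploit cooperators, and
cooperators respond by defecting too. A line of laboratory experiments
showed that simple autonomous agents ("bots") embedded in such networks
can reverse this decay — not by playing cleverly themselves, but by
intervening in *partner selection*: offering their human neighbor the
chance to cut a tie to a defector, or to form a tie to a cooperator.
`coopbots` re-implements that paradigm in silico: the game mechanics, six
bot policies, and a calibrated stochastic model of human cooperation and
rewiring decisions, so that the group-level dynamics can be reproduced,
probed, and extended without running new human experiments.

It is aimed at researchers in evolutionary game theory, social network
dynamics, and human-AI hybrid systems who want a reproducible sandbox for
network-intervention policies.

## The model

**Game.** 16 humans (plus condition-specific bots) start on an
Erdős–Rényi G(n, p = 0.3) network and play 30 rounds. Each round every
player either cooperates — paying \$0.05 per neighbor so that every
neighbor gains \$0.10 — or defects, paying and giving nothing. Actions are
then revealed, and a rewiring lottery selects each human pair
independently with probability 0.05; one member of a selected pair may
unilaterally break the tie (if present) or form it (if absent), knowing
only the counterpart's last action.

**Bot conditions.** `no_bot`; 16 single-tie bots playing always-cooperate
or tit-for-tat (controls); 16 single-tie bots that additionally hand
their neighbor one extra rewiring option per round chosen by a `random`,
`engaged` (make a tie to a cooperator) or `disengaged` (break a tie to a
defecting neighbor) criterion; and `single_mixed` — one bot with 5 ties
that rewires itself away from defecting neighbors, offers disengagement
to cooperating neighbors with defector contacts, and offers engagement
once a neighborhood is all-cooperative.

**Humans.** A human cooperates at round 1 with probability p₀ and
afterwards with probability

    P(C) = σ( β₀ + β_prev·1[prev = C] + β_k·k + β_c·c + β_kc·k·c + β_t·t )

where k is their degree and c the number of neighbors who cooperated last
round (conditional cooperation: β_k < 0, β_c > 0). Rewiring offers are
accepted with probabilities conditioned on (make/break × counterpart's
last action), defaulting to (0.7, 0.1, 0.9, 0.3) for break-with-defector,
break-with-cooperator, make-with-cooperator, make-with-defector. The
shipped decision coefficients are calibrated **only** against the no-bot
control trajectory (68.2% initial cooperation decaying to 36.4% at round
30); every cross-condition difference the simulator produces is therefore
a mechanistic prediction of the bot policies, not a fit. See
`docs/methods.md` for the calibration procedure and parameter rationale.

## Worked example

```python
import numpy as np
from coopbots import Condition, SessionConfig, run_session, cooperation_fraction

for cond in (Condition.NO_BOT, Condition.DISENGAGED_INT):
    r1, r30 = [], []
    for seed in range(8):
        res = run_session(SessionConfig(condition=cond, seed=seed))
        r1.append(cooperation_fraction(res.rounds[0], res.humans))
        r30.append(cooperation_fraction(res.rounds[-1], res.humans))
    print(f"{cond.value:12s} round 1: {np.mean(r1):.3f}   round 30: {np.mean(r30):.3f}")
```

prints

```
no_bot       round 1: 0.633   round 30: 0.398
disengaged   round 1: 0.641   round 30: 0.867
```

Over these 8 seeds per condition, unassisted groups decay from ~63% to
~40% cooperation, while groups whose bots quarantine defectors *rise* to
~87% — the qualitative signature of the disengaged network intervention.
A `SessionResult` also carries per-round payoffs, every rewiring option
issued and its fate, and tie snapshots, which `coopbots.io` writes as
tidy CSVs and `coopbots.metrics` turns into condition summaries,
cooperator-clustering indices, and round-trend regressions.

The same experiments are scriptable from the shell:

```
coopbots run --condition disengaged --sessions 8 --seed 0 --out out/
coopbots analyze --in out/
coopbots experiment --design paper_full --seed 0 --out exp/
```

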