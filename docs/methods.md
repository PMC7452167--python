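# Methods

## The simulated paradigm

One *session* is a 16-human group playing a 30-round networked
public-goods game. The initial human network is Erdős–Rényi G(n, p):
each of the C(16,2) = 120 human pairs is tied independently with
probability `initial_density` (default 0.30), so the *expected* tie count
is 36 and the expected human degree 4.5 — the density holds on average,
not exactly, matching a protocol that wires each pair by an independent
coin flip. Depending on the condition, bots are then attached: one
single-tie bot per human (a perfect matching; bots never tie to each
other), or one five-tie bot, or none.

Each round proceeds in a fixed phase order:

1. **Decisions.** All humans and bots choose cooperate/defect
   simultaneously, using only information revealed through the previous
   round.
2. **Payoffs.** A cooperator pays `coop_cost_per_neighbor` (default
   \$0.05) per tie; every node receives `benefit_to_each_neighbor`
   (default \$0.10) per cooperating neighbor. Payoffs accumulate on top
   of the \$1.00 endowment; balances may go negative (no bankruptcy
   rule). Bots are scored purely as bookkeeping. Each round the deltas
   sum to `cost × Σ_{cooperators} degree`, an identity the test suite
   asserts on the decision-time network.
3. **Revelation.** This round's actions become public to neighbors.
4. **Self-rewiring** (single-bot condition only, from round 2 onward):
   the mixed-strategy bot moves its own ties before any human options
   are generated, so its suggestions refer to the post-move network.
5. **Lottery.** Each human pair enters independently with probability
   `lottery_rate` (default 0.05, i.e. 6 expected options per round); a
   tied pair yields a break offer, an untied pair a make offer, and the
   decider is drawn uniformly from the two.
6. **Bot options.** In the intervention conditions every bot issues at
   most one extra option to its human neighbor (16 more options per
   round, raising rewiring coverage from 6/136 ≈ 5% to 22/136 ≈ 16% of
   possible connections).
7. **Resolution.** Every option is accepted or rejected independently by
   its decider; accepted options are applied in issuance order (lottery
   first, then bots in id order), and an option whose precondition was
   destroyed by an earlier application is skipped and logged rather than
   applied inconsistently.

All randomness flows through one `numpy` generator seeded from the
session config, so a session is a pure function of `(config, seed)`;
experiment batches spawn per-session seeds from a master seed with
`SeedSequence`.

## The human model

Humans are exchangeable: only their local situation enters the decision,
never their identity. At round 1 a human cooperates with probability
`p0`. From round 2 the cooperation probability is

    P(C) = logistic(b_intercept + b_prev·[prev = C] + b_degree·k
                    + b_coop·c + b_inter·k·c + b_round·t)

with `k` the current degree, `c` the number of neighbors (bots included —
subjects cannot distinguish them) who cooperated in the previous round,
and `t` the round index. Rewiring acceptance is Bernoulli with a
probability looked up by (make/break, counterpart's last action):
`p_break_d = 0.7`, `p_break_c = 0.1`, `p_make_c = 0.9`, `p_make_d = 0.3`.
These four values favor pruning defectors and courting cooperators, the
tie-preference regularity reported across dynamic-network cooperation
experiments; they are modeling defaults, not measured quantities.
`bot_source_mult` (default 1.0) scales the acceptance odds of bot-sourced
offers; the neutral default encodes the empirical null effect of making
the bots visible.

### Default decision coefficients and why

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `p0` | 0.682 | probability | observed grand-mean initial cooperation across the 48 first-experiment groups |
| `b_prev` | 1.5 | logit | behavioral inertia; moderate stickiness without freezing trajectories |
| `b_degree` | −0.42 | logit/neighbor | more neighbors make cooperation costlier and less likely |
| `b_coop` | +0.50 | logit/cooperating neighbor | conditional cooperation |
| `b_inter` | 0.0 | logit/(neighbor²) | no curvature needed once the two main effects carry the geometry |
| `b_round` | +0.001 | logit/round | calibrated; effectively zero — decay is emergent, not secular |
| `b_intercept` | +0.400 | logit | calibrated against the no-bot endpoints |

The structural choice that matters is `b_coop ≈ |b_degree|` with a
slightly positive sum (+0.08): gaining or losing a **cooperating**
neighbor then barely moves the cooperation probability (the move runs
almost parallel to the probability contours), while gaining or losing a
**defecting** neighbor shifts the logit by nearly the full `b_degree`.
Group dynamics are therefore driven by defector ties. This geometry is
what the estimated cooperation surface of the original experiments
shows, and it has two independent corroborations inside the simulator:
always-cooperate bots (a permanent extra cooperating neighbor) barely
change the trajectory, and the decay of unassisted groups emerges from
defectors degrading their neighbors' environments rather than from a
time trend (the calibrated `b_round` is ~0).

### Calibration

`coopbots.humans.calibrate` fits the model **only** to the no-bot
control: `p0` is set directly to the round-1 target (0.682) and the free
coefficients are searched by Nelder–Mead simplex (derivative-free; the
objective is noisy and 5-dimensional at most) within a bounded box,
minimizing the squared error between the simulated mean no-bot endpoint
trajectory and the targets (round-30 mean 0.364). Every evaluation
simulates the same fixed set of session seeds (common random numbers),
which keeps simplex comparisons meaningful at ~200 evaluations. The
shipped defaults used 200 sessions per evaluation; the structural
coefficients (`b_prev`, `b_degree`, `b_coop`, `b_inter`) were selected
beforehand on the qualitative grounds above and held fixed during the
endpoint fit.

Because nothing about the bot conditions enters the calibration, the
simulated cross-condition pattern — engaged below the no-bot control,
random above it, disengaged highest and *rising* above its own starting
level, cooperator clustering strongest under disengagement, a positive
round-trend only for disengagement — is a mechanistic prediction, and it
is what the acceptance suite checks.

## What the generator does and does not emulate

Emulated: the ~68% initial cooperation rate; decay of unassisted groups
to ~36%; cooperation increasing in cooperative neighbors and decreasing
in degree; inertia in individual choices; preferential tie-breaking with
defectors and tie-making with cooperators; the session-to-session
spread of outcomes (trajectories are strongly bimodal, as in the human
data where individual sessions locked into high or low cooperation).

Not emulated: individual heterogeneity (one parameter set for all
agents), learning or strategic sophistication beyond the one-step
conditional rule, degree-dependent saturation of the appetite for new
ties, and any response to earnings. Consequences visible in the
simulator's own output: the engaged condition, whose bots continually
attach defectors to cooperators, overshoots the observed decline (humans
accept almost every cooperator tie at `p_make_c = 0.9` regardless of how
many ties they already have); the random condition lands between the
no-bot control and disengagement but below its observed level; and in
single-bot sessions the residual ~30% defection stays spatially mixed
enough that the "whole neighborhood cooperates" trigger for the engaged
branch fires less often than observed late in the human sessions.
Passing tests therefore certify the game mechanics, the bot policies,
and the directional group-level predictions — not quantitative accuracy
for every condition.

## Numerical and design choices

- **Decision covariates**: round-t decisions use the post-rewiring
  network of round t−1 and the actions revealed at t−1. Round 1 has no
  history and uses `p0` alone.
- **Option independence**: a human holding several options in one round
  (lottery plus bot) resolves each independently; the experiment's
  protocol for this case is unreported and independence is the simplest
  contract.
- **Sequential-with-skip application** avoids contradictory tie states
  when two accepted options touch the same pair; the skip is logged.
- **Mixed bot fallbacks**: a defecting neighbor is kept when no
  replacement cooperator exists (the bot never dangles, so its degree
  stays 5); an engage offer is dropped when no untied cooperator exists.
  Branch selection scans the bot's neighbor list in id order.
- **Interaction centering**: the recovery regression in
  `coopbots.metrics` subtracts the mean of the raw product k·c, which
  shifts only the intercept and keeps all slopes on the generating
  scale.
- **Trend regression**: per-condition round slopes come from a logistic
  regression with cluster-robust (session-level) covariance. A
  frequentist binary-response mixed model is not available in the
  installed stack, so the hierarchical random-intercept variant is
  replaced by this documented fallback and the method is recorded in the
  result metadata (`logit_cluster_cr`). Separation or non-convergence
  yields a flagged NaN estimate, never a crash.
- **Clustering is reported twice** — the fraction of human–human ties
  joining two cooperators, and the attribute assortativity of the binary
  action on the human subgraph — because the original clustering metric
  is not specified; both are standard, and undefined cases (no human
  ties, or a single strategy present) return NaN rather than 0.
- **Problem sizes**: the test and acceptance runs use the original
  design sizes where they are small (48-session layout, 200 sessions per
  condition for endpoint means, 100 single-bot sessions) and scale down
  only Monte-Carlo conveniences such as lottery-frequency replicates;
  each scaled check carries its own standard-error-based tolerance.

## Known limitations

- Quantitative final-round levels for the engaged and random conditions
  fall below their observed values (see above); the ordering and the
  disengaged rise are robust across seeds, the levels are not tuned.
- The single-bot engaged-branch share rises steeply with a session's
  cooperation level but does not reach a late-round majority under the
  shipped parameters.
- Rewiring acceptance does not depend on the decider's own degree,
  previous action, or earnings; all are plausible moderators in humans.
- No payout-relevant behavior (risk, wealth effects) is modeled; the
  earnings ledger is bookkeeping.
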