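# Methods

## Task model

A trial is a finite-horizon Markov decision process over two goals. The
state is the pair of distance-to-resolution counters `(d1, d2)` plus
per-goal resolution flags; the action is which goal to prioritize. Both
goal frames reduce to the same decrementing-counter mechanics:

* **Approach** ("score 10 or more"): a goal starting at score `s` needs
  `d = 10 − s` more points. A successful step decrements `d`; `d = 0`
  means achieved. The prioritized goal's step succeeds with probability
  `p_prioritized` (default 0.8), the other goal's independently with
  `p_nonprioritized` (default 0.2).
* **Avoidance** ("never drop to 9 or less"): a goal starting at `s` can
  absorb `d = s − 9` losses. An *unsuccessful* step costs a point, so the
  prioritized goal loses with probability `1 − 0.8 = 0.2` and the
  non-prioritized goal with `1 − 0.2 = 0.8`; `d = 0` means failed. A goal
  still pending at the horizon counts as attained.

Assumptions: at most one unit of progress/loss per goal per stage;
per-goal outcomes are independent Bernoulli draws; resolution is absorbing
(scores cannot overshoot the thresholds, resolved goals are frozen);
transition probabilities are known, stationary and state-independent.

Terminal value is the attained-goal count, so backward induction
(`mdp.backward_induction`) maximizes the expected number of attained
goals. The value table is indexed by stages *remaining*, which makes one
table reusable across trials of different horizons. The forward pass
(`mdp.attainment_probabilities`) propagates the start state through the
policy and reports `(p_both, p_one, p_none)`; it satisfies the identity
`2·p_both + p_one = v(start)` under the optimal policy.

### Numerical choices

* Probabilities are stored as exact `Fraction`s (floats are parsed via
  their decimal representation, so `0.8` is 4/5).
* The solver runs in floating point by default; `exact=True` switches the
  whole recursion to rational arithmetic. Ties between the two actions'
  expected values are exact equality in rational mode and `|Δe| < 1e-12`
  in float mode. Genuine ties exist beyond the symmetric `d1 = d2` states
  (e.g. approach, distances (1, 2), two stages remaining), so tie
  detection matters for decision coding.
* In the forward pass, tie states split probability 1/2–1/2 between the
  actions. The choice is inconsequential for symmetric ties and unbiased
  for asymmetric ones; tied decisions are excluded from analysis anyway.
* Degenerate inputs: a start state with both goals resolved has attainment
  probability concentrated on its terminal value; requesting a transition
  from a fully resolved state raises `BothGoalsResolvedError`.

## Design reconstruction

The experiment crossed goal frame × dual-goal difficulty × relative
position (starting score gap 0, 1, 3 or 5), 24 conditions, 6 repetitions,
20 participants, horizons 11–24 decisions. Difficulty was defined by the
probability of attaining both goals from the start: low [.95, .96],
moderate [.57, .58], high [.03, .06]. The exact per-condition starting
scores were not published, so `design.calibrate_condition` searches the
integer grid — ascending horizon 11…24, then ascending starting deficit,
with the worse goal offset by the relative position — for the first task
whose **optimal-policy** dual-attainment probability lies in the band.

Decisions made where the design was genuinely open:

* **Reference policy.** The published bands do not say under which policy
  the attainment probability was computed; we use the optimal policy, the
  only participant-independent benchmark the model provides.
* **Band fallback.** The achievable probabilities form a discrete set, and
  exhaustive search shows a few cells have no grid point inside their
  (width .01) band under any reference policy we tried. For those cells
  the calibrator takes the nearest achievable value on the side that
  preserves the difficulty ordering — easier than the band for "low",
  harder for "high", nearest for "moderate" — and flags `in_band=False`.
  In the default design this affects four cells (three moderate at
  .561–.569, one high pair at .022/.0099); low cells are all strictly in
  band (minimum .9523) and high cells all at or below .0342. The fallback
  applies only to the published default bands; user-supplied bands are
  searched strictly and raise `NoFeasibleCondition` when unreachable.
* **Counterbalancing.** Which on-screen goal leads is alternated by
  repetition (goal 1 leads in odd repetitions). Per-participant trial
  order is an independent seeded shuffle.
* The scanner used in the calibration loop is a vectorized lattice
  implementation; every chosen condition is re-verified against the
  state-indexed solver to 1e-9 before being accepted, and the tests check
  it a third way by explicit transition-matrix propagation.

## Synthetic participants

No generative choice process is specified for humans, only the
directional hypothesis (risk-averse under approach, risk-seeking under
avoidance). The simulator therefore uses the smallest rule nesting
optimal play:

    P(choose worse-position goal) = σ(β·(EV_worse − EV_better) + bias_frame)

with inverse temperature `β ≥ 0` (logit units per expected goal) and an
additive frame-specific preference for the worse-position goal. The
*worse-position* goal is the lower-score goal in both frames (the larger
points deficit under approach; the smaller loss buffer under avoidance).
After one goal resolves, agents prioritize the pending goal; such
decisions are excluded from analysis but keep log lengths faithful.

Default population: `β = 12`, `bias_approach = −0.8`,
`bias_avoidance = +0.8`, per-participant biases jittered with SD 0.25.
These values were fixed by a design-time scan so that the simulated
qualitative pattern is robust across seeds: a finite temperature drags
both sources toward indifference (0.5), so too-weak biases cannot express
the avoidance direction at all. At these defaults the full-scale simulated
effects are of the same order as the human tendencies the task was built
to measure (worse-position prioritization ≈ .29 vs the model's .49 under
approach, ≈ .70 vs .62 under avoidance, interaction β ≈ −0.3).

The diminishing-returns agent re-solves the MDP with subjective terminal
utilities `u(0) = 0, u(1) = 1, u(2) = 1 + c` (`c = utility_second_goal`)
and plays its argmax; `c = 1` reproduces the objective policy exactly,
while small `c` makes the agent secure one goal rather than gamble for
two.

Randomness: every (participant, trial) pair gets its own
`numpy.random.Generator` seeded by `[master_seed, participant, trial]`, so
datasets are reproducible and independent of simulation order.

**What the generator does not emulate:** learning or experience effects
(probabilities are known and stationary), reaction times, trial-order or
fatigue effects, the house-money effect of accumulated winnings, and any
within-trial dynamics of the bias. Passing tests therefore show that the
*pipeline* recovers the biases a logistic agent was given — not that
human departures from optimality follow a logistic law.

## Analysis

Coding: a kept decision is `worse_coded = 1` if it prioritized the
lower-score goal; the corresponding optimal decision is coded on the same
scale from the value table. Exclusions, in precedence order: a goal
already resolved, equal scores (no worse position exists), exact
expected-value tie (no optimal decision exists). Exclusion is idempotent
and tallied per reason; at full scale roughly 40% of logged decisions are
excluded, comparable to the original task's yield.

Each kept decision contributes two rows (participant, model), and

    logit P(worse) = β0 + β1·frame + β2·source + β3·frame×source

is fitted with frame (+1 approach, −1 avoidance) and source
(+1 participant, −1 model). The reference analysis used a logistic
mixed-effects model with random effects of participant and trial; exact
random-effects estimation is out of scope, so the model is fitted by
in-repo IRLS (deviance tolerance 1e-8, max 100 iterations, separation
flagged at `|β| > 15`) with participant-clustered sandwich standard
errors (CR1 small-sample correction). This preserves the inferential
target — the sign and approximate magnitude of the interaction — but
coefficient magnitudes should be compared qualitatively, not
digit-for-digit. Whether "trial" in the reference analysis means trial
identity or condition is ambiguous; we cluster on participant only. No
multiple-testing correction is applied (one planned interaction plus two
follow-ups). The statsmodels GLM implementation serves as an independent
cross-check of coefficients and clustered errors in the test suite.

Follow-up models regress worse-position prioritization on source alone
within each frame; `summarize_proportions` reports the four frame × source
cell proportions with Wilson 95% intervals.

## Problem sizes

The package's own test and acceptance runs use the full 24-condition
design throughout; simulation-based checks use 3–6 participants with 1–2
repetitions (2–6 thousand decisions), 6–8 thousand Monte-Carlo trials for
attainment frequencies, and 20 seeded replicates for the sign-recovery
check. The full published scale (20 participants × 144 trials, ≈36,000
decisions) runs in a few seconds via `goalpursuit pipeline`.

## Known limitations

* The calibrated conditions are a *reconstruction*: the published
  per-condition scores and horizons are unavailable, and four cells sit
  just outside their published band (flagged `in_band=False`). Decision
  counts therefore match the published totals only approximately.
* Exactly two goals; no state-dependent or learned transition
  probabilities; no continuous-time reprioritization.
* The human coefficients cannot be reproduced — the participant data are
  not public — so the analysis is validated by parameter recovery on
  synthetic agents instead.
* Fixed-effects-plus-clustering is an approximation to the original
  mixed-effects estimation (above).
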