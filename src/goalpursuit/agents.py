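"""Synthetic participants: optimal and risk-biased choice rules, trial simulation.

The experimental hypothesis is directional: under approach framing people
prioritize the worse-position (lower-score) goal *less* often than the
normative model (risk aversion); under avoidance framing *more* often
(risk seeking). No generative choice process is specified, so the
simulator uses a minimal logistic rule that nests optimal play:

    P(choose worse-position goal)
        = sigmoid(beta * (EV_worse - EV_better) + bias_frame)

where ``beta`` is an inverse temperature (sensitivity to the expected-value
difference between actions) and ``bias_frame`` is an additive preference
for the worse-position goal — negative in approach and positive in
avoidance reproduces the hypothesized pattern. ``beta -> inf`` with zero
bias recovers the optimal agent.

A third agent implements diminishing returns: backward induction is re-run
with subjective terminal utilities u(0) = 0, u(1) = 1,
u(2) = 1 + ``utility_second_goal``, and the agent plays that argmax. With
``utility_second_goal = 1`` the subjective and objective solutions agree.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable, Union

import numpy as np
import pandas as pd

from .design import Condition, DesignTable, build_schedule
from .mdp import (
    Action,
    BothGoalsResolvedError,
    GoalFrame,
    GoalStatus,
    JointState,
    TaskSpec,
    ValuePolicyTable,
    backward_induction,
    enumerate_states,
    expected_value,
    terminal_value,
)

__all__ = [
    "AgentKind",
    "AgentParams",
    "TrialLog",
    "choose",
    "simulate_trial",
    "generate_dataset",
    "default_population",
    "DECISION_COLUMNS",
]

#: Pence gained (approach) or lost (avoidance) per goal.
PENCE_PER_GOAL = 3


class AgentKind(str, enum.Enum):
    OPTIMAL = "optimal"
    LOGISTIC_BIASED = "logistic_biased"
    DIMINISHING_RETURNS = "diminishing_returns"


@dataclass(frozen=True)
class AgentParams:
    """Choice-rule parameters.

    inverse_temperature : float >= 0
        Sensitivity of the logistic rule to the EV difference (logit units
        per expected goal). 0 means EV-blind coin flips.
    bias_approach, bias_avoidance : float
        Additive logit preference for the worse-position goal under each
        frame. Ignored by the optimal agent.
    utility_second_goal : float in (0, 1]
        Marginal utility of the second attained goal for the
        diminishing-returns agent; 1 recovers the objective values.
    """

    kind: AgentKind = AgentKind.OPTIMAL
    inverse_temperature: float = 5.0
    bias_approach: float = 0.0
    bias_avoidance: float = 0.0
    utility_second_goal: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", AgentKind(self.kind))
        if self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be >= 0")
        if not 0 < self.utility_second_goal <= 1:
            raise ValueError("utility_second_goal must be in (0, 1]")

    def bias(self, frame: GoalFrame) -> float:
        return self.bias_approach if GoalFrame(frame) is GoalFrame.APPROACH else self.bias_avoidance


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


@lru_cache(maxsize=512)
def _subjective_table(spec: TaskSpec, utility_second_goal: float) -> ValuePolicyTable:
    """Backward induction under concave terminal utility u(2) = 1 + c."""
    u = {0: 0.0, 1: 1.0, 2: 1.0 + utility_second_goal}
    states = enumerate_states(spec)
    v = [{s: u[terminal_value(s, spec.frame)] for s in states}]
    q: list[dict] = [{}]
    for _ in range(spec.horizon):
        v_next = v[-1]
        q_slice = {}
        v_slice = {}
        for s in states:
            e1 = expected_value(s, Action.GOAL1, v_next, spec, exact=False)
            e2 = expected_value(s, Action.GOAL2, v_next, spec, exact=False)
            q_slice[s] = (e1, e2)
            v_slice[s] = max(e1, e2)
        q.append(q_slice)
        v.append(v_slice)
    return ValuePolicyTable(spec, q, v, exact=False)


def _worse_goal(frame: GoalFrame, state: JointState) -> Action | None:
    """The lower-score (worse-position) goal, or None if scores are equal.

    Approach: lower score = larger points deficit. Avoidance: lower score =
    smaller loss buffer.
    """
    if state.d1 == state.d2:
        return None
    farther = Action.GOAL1 if state.d1 > state.d2 else Action.GOAL2
    if GoalFrame(frame) is GoalFrame.APPROACH:
        return farther
    return Action.GOAL2 if farther is Action.GOAL1 else Action.GOAL1


def _coin(rng: np.random.Generator) -> Action:
    return Action.GOAL1 if rng.random() < 0.5 else Action.GOAL2


def choose(
    agent: AgentParams,
    state: JointState,
    remaining: int,
    table: ValuePolicyTable,
    frame: GoalFrame,
    rng: np.random.Generator,
) -> Action:
    """One prioritization decision.

    Once a goal has resolved the pending goal is prioritized regardless of
    agent kind (such decisions are excluded from analysis). EV ties and
    equal-score states resolve by fair coin.
    """
    if state.both_resolved:
        raise BothGoalsResolvedError("both goals are resolved; no decision exists")
    if state.any_resolved:
        return Action.GOAL1 if state.status1 is GoalStatus.PENDING else Action.GOAL2

    if agent.kind is AgentKind.OPTIMAL:
        a = table.action(state, remaining)
        return _coin(rng) if a is Action.TIE else a

    if agent.kind is AgentKind.DIMINISHING_RETURNS:
        sub = _subjective_table(table.spec, agent.utility_second_goal)
        a = sub.action(state, remaining)
        return _coin(rng) if a is Action.TIE else a

    # logistic rule on the worse-minus-better EV difference
    worse = _worse_goal(frame, state)
    q1, q2 = table.q(state, remaining)
    if worse is None:
        p_goal1 = _sigmoid(agent.inverse_temperature * float(q1 - q2))
        return Action.GOAL1 if rng.random() < p_goal1 else Action.GOAL2
    q_worse, q_better = (q1, q2) if worse is Action.GOAL1 else (q2, q1)
    x = agent.inverse_temperature * float(q_worse - q_better) + agent.bias(frame)
    if rng.random() < _sigmoid(x):
        return worse
    return Action.GOAL2 if worse is Action.GOAL1 else Action.GOAL1


@dataclass(frozen=True)
class TrialLog:
    """One simulated trial: the decision sequence plus outcome bookkeeping."""

    participant: int
    trial: int
    condition_id: str
    frame: GoalFrame
    decisions: tuple[dict, ...]
    final_state: JointState
    goals_attained: int
    money_delta_pence: int

    def to_rows(self) -> list[dict]:
        return [dict(d) for d in self.decisions]


def simulate_trial(
    condition: Condition,
    agent: AgentParams,
    rng: np.random.Generator,
    table: ValuePolicyTable | None = None,
    participant: int = 1,
    trial: int = 1,
    swap_goals: bool = False,
) -> TrialLog:
    """Play one trial decision-by-decision.

    Per-decision outcomes are independent Bernoulli draws with the spec's
    progress probabilities. ``swap_goals`` mirrors the on-screen goal order
    (counterbalancing which goal starts ahead); the mirrored task is solved
    on its own (cached) table.
    """
    spec = condition.spec
    if swap_goals:
        spec = replace(spec, d_start=(spec.d_start[1], spec.d_start[0]))
    if table is None or table.spec != spec:
        table = _cached_table(spec)
    frame = spec.frame
    d1, d2 = spec.d_start
    rows = []
    for stage in range(1, spec.horizon + 1):
        remaining = spec.horizon - stage + 1
        state = JointState.make(frame, d1, d2)
        if state.both_resolved:
            # trial keeps running for log-length fidelity; nothing to decide
            action = _coin(rng)
            step1 = step2 = False
        else:
            action = choose(agent, state, remaining, table, frame, rng)
            p1 = spec.p_prioritized if action is Action.GOAL1 else spec.p_nonprioritized
            p2 = spec.p_prioritized if action is Action.GOAL2 else spec.p_nonprioritized
            if frame is GoalFrame.AVOIDANCE:
                p1, p2 = 1 - p1, 1 - p2
            step1 = state.status1 is GoalStatus.PENDING and rng.random() < float(p1)
            step2 = state.status2 is GoalStatus.PENDING and rng.random() < float(p2)
        rows.append(
            {
                "participant": participant,
                "trial": trial,
                "condition_id": condition.condition_id,
                "frame": frame.value,
                "difficulty": condition.difficulty.value,
                "relative_position": condition.relative_position,
                "horizon": spec.horizon,
                "stage": stage,
                "remaining": remaining,
                "d1": d1,
                "d2": d2,
                "d1_start": spec.d_start[0],
                "d2_start": spec.d_start[1],
                "score1": spec.score_of(d1),
                "score2": spec.score_of(d2),
                "status1": state.status1.value,
                "status2": state.status2.value,
                "chosen": action.value,
                "outcome1": int(step1),
                "outcome2": int(step2),
            }
        )
        d1 -= int(step1)
        d2 -= int(step2)
    final = JointState.make(frame, d1, d2)
    attained = terminal_value(final, frame)
    if frame is GoalFrame.APPROACH:
        money = PENCE_PER_GOAL * attained
    else:
        money = -PENCE_PER_GOAL * (2 - attained)
    return TrialLog(
        participant, trial, condition.condition_id, frame, tuple(rows), final, attained, money
    )


@lru_cache(maxsize=512)
def _cached_table(spec: TaskSpec) -> ValuePolicyTable:
    return backward_induction(spec)


PopulationSpec = Union[AgentParams, Callable[[int, np.random.Generator], AgentParams]]


def default_population(
    bias_approach: float = -0.8,
    bias_avoidance: float = 0.8,
    inverse_temperature: float = 12.0,
    bias_sd: float = 0.25,
) -> Callable[[int, np.random.Generator], AgentParams]:
    """Participant population with frame-dependent risk biases.

    Mean biases are negative for approach (risk-averse underprioritization
    of the worse-position goal) and positive for avoidance (risk-seeking
    overprioritization); per-participant biases jitter around the means.
    The inverse temperature is high enough that the additive biases, not
    the softmax's pull toward indifference, dominate the departure from
    the optimal model — the regime the directional hypothesis describes.
    """

    def make(participant: int, rng: np.random.Generator) -> AgentParams:
        return AgentParams(
            kind=AgentKind.LOGISTIC_BIASED,
            inverse_temperature=inverse_temperature,
            bias_approach=bias_approach + bias_sd * rng.standard_normal(),
            bias_avoidance=bias_avoidance + bias_sd * rng.standard_normal(),
        )

    return make


DECISION_COLUMNS = [
    "participant",
    "trial",
    "condition_id",
    "frame",
    "difficulty",
    "relative_position",
    "horizon",
    "stage",
    "remaining",
    "d1",
    "d2",
    "d1_start",
    "d2_start",
    "score1",
    "score2",
    "status1",
    "status2",
    "chosen",
    "outcome1",
    "outcome2",
]


def generate_dataset(
    design: DesignTable,
    agent_population: PopulationSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the whole experiment: one row per decision.

    Per-(participant, trial) RNG streams are derived from the master seed
    with ``np.random.default_rng([seed, participant, trial])``, so any
    trial can be regenerated in isolation and row order never matters.
    """
    if agent_population is None:
        agent_population = default_population()
    schedule = build_schedule(design, seed)
    all_rows: list[dict] = []
    agents: dict[int, AgentParams] = {}
    for row in schedule.itertuples(index=False):
        pid = int(row.participant)
        if pid not in agents:
            if isinstance(agent_population, AgentParams):
                agents[pid] = agent_population
            else:
                agents[pid] = agent_population(pid, np.random.default_rng([seed, pid, 0]))
        condition = design.condition(row.condition_id)
        rng = np.random.default_rng([seed, pid, int(row.trial)])
        log = simulate_trial(
            condition,
            agents[pid],
            rng,
            participant=pid,
            trial=int(row.trial),
            swap_goals=(row.lead_goal == 2 and condition.relative_position > 0),
        )
        for r in log.to_rows():
            r["repetition"] = int(row.repetition)
            all_rows.append(r)
    return pd.DataFrame(all_rows, columns=DECISION_COLUMNS + ["repetition"])
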