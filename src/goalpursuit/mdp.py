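"""Finite-horizon Markov decision process for two-goal pursuit.

A trial confronts an agent with two concurrent goals, framed either as
*approach* goals (reach a score of at least 10 before the deadline) or as
*avoidance* goals (never let a score drop to 9 or below). At each of ``T``
discrete stages the agent prioritizes exactly one goal. The prioritized
goal makes a step of progress with probability ``p_prioritized`` and the
other goal, independently, with probability ``p_nonprioritized``.

Both frames are represented by a per-goal *distance-to-resolution* counter
``d``:

* approach — ``d`` is the number of points still needed; a successful step
  decrements ``d``; ``d = 0`` means the goal is **achieved**.
* avoidance — ``d`` is the buffer of losses the goal can absorb (start
  score minus 9); an unsuccessful step costs a point and decrements ``d``;
  ``d = 0`` means the goal has **failed**. A goal still pending when the
  horizon runs out has been successfully avoided.

Terminal value is the number of attained goals (0, 1 or 2), so the optimal
policy recovered by backward induction maximizes the expected number of
attained goals. Expected action values are

    e_a(t) = sum_s p(s | a) * v_s(t)

and state values satisfy ``v_s(t) = max_a e_{s|a}(t + 1)``, with the
recursion anchored at the horizon by the terminal count of attained goals.

All probabilities are stored as :class:`fractions.Fraction`; the solver
runs in floating point by default and in exact rational arithmetic with
``exact=True`` (ties are then detected exactly).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, NamedTuple, Union

import pandas as pd

__all__ = [
    "GoalFrame",
    "GoalStatus",
    "Action",
    "TaskSpec",
    "JointState",
    "ValuePolicyTable",
    "AttainmentProbs",
    "BothGoalsResolvedError",
    "APPROACH_THRESHOLD",
    "AVOIDANCE_THRESHOLD",
    "TIE_TOL",
    "enumerate_states",
    "terminal_value",
    "transition_distribution",
    "expected_value",
    "backward_induction",
    "attainment_probabilities",
]

#: Approach goals succeed at a score of at least this many points.
APPROACH_THRESHOLD = 10
#: Avoidance goals fail at a score of this many points or fewer.
AVOIDANCE_THRESHOLD = 9

#: Absolute tolerance for declaring two floating-point action values tied.
TIE_TOL = 1e-12

Number = Union[float, Fraction]


class GoalFrame(str, enum.Enum):
    """Whether the pair of goals is framed as gains or as threatened losses."""

    APPROACH = "approach"
    AVOIDANCE = "avoidance"


class GoalStatus(str, enum.Enum):
    PENDING = "pending"
    ACHIEVED = "achieved"
    FAILED = "failed"


class Action(str, enum.Enum):
    """Which goal is prioritized; TIE marks equal expected values."""

    GOAL1 = "goal1"
    GOAL2 = "goal2"
    TIE = "tie"


class BothGoalsResolvedError(ValueError):
    """Raised when a decision is requested in a state with no pending goal."""


def _as_prob(x: Union[float, str, Fraction]) -> Fraction:
    """Coerce a probability to an exact Fraction (floats via their decimal repr)."""
    if isinstance(x, Fraction):
        p = x
    elif isinstance(x, float):
        p = Fraction(str(x))
    else:
        p = Fraction(x)
    if not 0 <= p <= 1:
        raise ValueError(f"probability out of [0, 1]: {x!r}")
    return p


@dataclass(frozen=True)
class TaskSpec:
    """One trial's two-goal MDP: frame, horizon and starting distances.

    Parameters
    ----------
    frame : GoalFrame
        Approach (gain) or avoidance (loss) framing.
    horizon : int
        Number of prioritization decisions in the trial, ``T >= 1``.
    d_start : (int, int)
        Starting distance-to-resolution of each goal (points needed under
        approach, loss buffer under avoidance).
    p_prioritized, p_nonprioritized : Fraction
        Per-stage probability that the prioritized / non-prioritized goal
        makes a step of progress. Defaults are the task's 0.8 and 0.2.
    """

    frame: GoalFrame
    horizon: int
    d_start: tuple[int, int]
    p_prioritized: Fraction = Fraction(4, 5)
    p_nonprioritized: Fraction = Fraction(1, 5)

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame", GoalFrame(self.frame))
        object.__setattr__(self, "d_start", (int(self.d_start[0]), int(self.d_start[1])))
        object.__setattr__(self, "p_prioritized", _as_prob(self.p_prioritized))
        object.__setattr__(self, "p_nonprioritized", _as_prob(self.p_nonprioritized))
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if min(self.d_start) < 0:
            raise ValueError("starting distances must be non-negative")

    @classmethod
    def from_scores(
        cls,
        frame: GoalFrame,
        scores: tuple[int, int],
        horizon: int,
        p_prioritized: Union[float, Fraction] = Fraction(4, 5),
        p_nonprioritized: Union[float, Fraction] = Fraction(1, 5),
    ) -> "TaskSpec":
        """Build a spec from on-screen scores.

        Approach: distance = 10 - score (points still needed). Avoidance:
        distance = score - 9 (losses the goal can absorb before failing).
        """
        frame = GoalFrame(frame)
        if frame is GoalFrame.APPROACH:
            d = (APPROACH_THRESHOLD - scores[0], APPROACH_THRESHOLD - scores[1])
        else:
            d = (scores[0] - AVOIDANCE_THRESHOLD, scores[1] - AVOIDANCE_THRESHOLD)
        if min(d) < 0:
            raise ValueError(f"scores {scores} invalid for frame {frame.value}")
        return cls(frame, horizon, d, p_prioritized, p_nonprioritized)

    def score_of(self, d: int) -> int:
        """On-screen score corresponding to distance ``d`` under this frame."""
        if self.frame is GoalFrame.APPROACH:
            return APPROACH_THRESHOLD - d
        return AVOIDANCE_THRESHOLD + d

    @property
    def start_scores(self) -> tuple[int, int]:
        return (self.score_of(self.d_start[0]), self.score_of(self.d_start[1]))

    @property
    def start_state(self) -> "JointState":
        return JointState.make(self.frame, self.d_start[0], self.d_start[1])

    def to_dict(self) -> dict:
        return {
            "frame": self.frame.value,
            "horizon": self.horizon,
            "start_scores": list(self.start_scores),
            "thresholds": {
                "approach": APPROACH_THRESHOLD,
                "avoidance": AVOIDANCE_THRESHOLD,
            },
            "p_prioritized": float(self.p_prioritized),
            "p_nonprioritized": float(self.p_nonprioritized),
            "d_start": list(self.d_start),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "TaskSpec":
        return cls(
            frame=GoalFrame(payload["frame"]),
            horizon=int(payload["horizon"]),
            d_start=tuple(payload["d_start"]),
            p_prioritized=_as_prob(payload.get("p_prioritized", Fraction(4, 5))),
            p_nonprioritized=_as_prob(payload.get("p_nonprioritized", Fraction(1, 5))),
        )


def _status_of(frame: GoalFrame, d: int) -> GoalStatus:
    if d > 0:
        return GoalStatus.PENDING
    return GoalStatus.ACHIEVED if frame is GoalFrame.APPROACH else GoalStatus.FAILED


@dataclass(frozen=True)
class JointState:
    """The environmental state: each goal's remaining distance and status.

    ``d`` is frozen once a goal resolves (at 0). Approach goals can only be
    pending or achieved; avoidance goals only pending or failed.
    """

    d1: int
    d2: int
    status1: GoalStatus
    status2: GoalStatus

    @classmethod
    def make(cls, frame: GoalFrame, d1: int, d2: int) -> "JointState":
        frame = GoalFrame(frame)
        return cls(d1, d2, _status_of(frame, d1), _status_of(frame, d2))

    @property
    def both_resolved(self) -> bool:
        return self.status1 is not GoalStatus.PENDING and self.status2 is not GoalStatus.PENDING

    @property
    def any_resolved(self) -> bool:
        return self.status1 is not GoalStatus.PENDING or self.status2 is not GoalStatus.PENDING

    @property
    def distances(self) -> tuple[int, int]:
        return (self.d1, self.d2)


def enumerate_states(spec: TaskSpec) -> set[JointState]:
    """All states reachable from the start, including absorbing resolutions.

    Each goal independently occupies one of ``d_start + 1`` positions
    (``d_start`` down to 0), so the joint space has
    ``(d1_start + 1) * (d2_start + 1)`` states.
    """
    return {
        JointState.make(spec.frame, a, b)
        for a in range(spec.d_start[0] + 1)
        for b in range(spec.d_start[1] + 1)
    }


def terminal_value(state: JointState, frame: GoalFrame) -> int:
    """Number of attained goals at the horizon (0, 1 or 2).

    Approach goals are attained iff achieved (d reached 0); avoidance
    goals are attained iff still pending at the horizon (never failed).
    """
    frame = GoalFrame(frame)
    if frame is GoalFrame.APPROACH:
        ok = GoalStatus.ACHIEVED
    else:
        ok = GoalStatus.PENDING
    return int(state.status1 is ok) + int(state.status2 is ok)


def _step_probability(spec: TaskSpec, prioritized: bool, exact: bool) -> Number:
    """Probability that a pending goal's distance decrements this stage."""
    p = spec.p_prioritized if prioritized else spec.p_nonprioritized
    if spec.frame is GoalFrame.AVOIDANCE:
        p = 1 - p  # a loss occurs when the action fails for that goal
    return p if exact else float(p)


def transition_distribution(
    state: JointState,
    action: Action,
    spec: TaskSpec,
    exact: bool = True,
) -> dict[JointState, Number]:
    """Distribution over successor states for one prioritization decision.

    Per-goal outcomes are independent Bernoulli draws; resolved goals are
    frozen. At most one unit of progress/loss per goal per stage.
    """
    action = Action(action)
    if action is Action.TIE:
        raise ValueError("a transition requires a concrete action (goal1 or goal2)")
    if state.both_resolved:
        raise BothGoalsResolvedError("both goals are resolved; no decision exists")

    one: Number = Fraction(1) if exact else 1.0
    dist: dict[JointState, Number] = {}
    p_step = (
        _step_probability(spec, action is Action.GOAL1, exact),
        _step_probability(spec, action is Action.GOAL2, exact),
    )
    pending = (state.status1 is GoalStatus.PENDING, state.status2 is GoalStatus.PENDING)
    for step1 in (False, True):
        for step2 in (False, True):
            pr = one
            for step, is_pending, p in zip((step1, step2), pending, p_step):
                if not is_pending:
                    if step:
                        pr = None  # frozen goal cannot move
                        break
                    continue
                pr = pr * (p if step else one - p)
            if pr is None or pr == 0:
                continue
            succ = JointState.make(
                spec.frame,
                state.d1 - int(step1 and pending[0]),
                state.d2 - int(step2 and pending[1]),
            )
            dist[succ] = dist.get(succ, one * 0) + pr
    return dist


def expected_value(
    state: JointState,
    action: Action,
    v_next: Mapping[JointState, Number],
    spec: TaskSpec,
    exact: bool = True,
) -> Number:
    """Probability-weighted value of successor states under ``action``.

    For a state with both goals resolved the value is absorbing and the
    action is irrelevant.
    """
    if state.both_resolved:
        try:
            return v_next[state]
        except KeyError:
            raise KeyError(f"missing successor value for absorbing state {state}") from None
    total: Number = Fraction(0) if exact else 0.0
    for succ, pr in transition_distribution(state, action, spec, exact=exact).items():
        try:
            total += pr * v_next[succ]
        except KeyError:
            raise KeyError(f"missing successor value for {succ}") from None
    return total


class ValuePolicyTable:
    """State values and optimal actions, indexed by stages remaining.

    Slice 0 holds terminal values; slice ``r`` (``1 <= r <= horizon``) holds
    the action values ``e_a`` and state value ``v`` when ``r`` decisions
    remain. Indexing by stages-remaining makes a table reusable across
    trials of different horizons that share the same spec mechanics.
    """

    def __init__(
        self,
        spec: TaskSpec,
        q: list[dict[JointState, tuple[Number, Number]]],
        v: list[dict[JointState, Number]],
        exact: bool,
    ):
        self.spec = spec
        self._q = q  # q[r][state] = (e_goal1, e_goal2), r >= 1
        self._v = v  # v[r][state]
        self.exact = exact

    @property
    def horizon(self) -> int:
        return self.spec.horizon

    def states(self) -> set[JointState]:
        return set(self._v[0])

    def q(self, state: JointState, remaining: int) -> tuple[Number, Number]:
        if not 1 <= remaining <= self.horizon:
            raise ValueError(f"remaining must be in [1, {self.horizon}]")
        return self._q[remaining][state]

    def v(self, state: JointState, remaining: int) -> Number:
        return self._v[remaining][state]

    def is_tie(self, state: JointState, remaining: int) -> bool:
        q1, q2 = self.q(state, remaining)
        if self.exact:
            return q1 == q2
        return abs(q1 - q2) < TIE_TOL

    def action(self, state: JointState, remaining: int) -> Action:
        """Optimal action with ``remaining`` decisions left; TIE if equal EVs."""
        q1, q2 = self.q(state, remaining)
        if self.is_tie(state, remaining):
            return Action.TIE
        return Action.GOAL1 if q1 > q2 else Action.GOAL2

    def start_value(self) -> Number:
        """Expected number of attained goals from the start under optimal play."""
        return self.v(self.spec.start_state, self.horizon)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (stage, state) with both EVs and the action.

        ``stage`` is 1-based calendar stage; ``remaining = horizon - stage + 1``.
        """
        rows = []
        for stage in range(1, self.horizon + 1):
            remaining = self.horizon - stage + 1
            for state in sorted(self._q[remaining], key=lambda s: (s.d1, s.d2)):
                q1, q2 = self._q[remaining][state]
                rows.append(
                    {
                        "stage": stage,
                        "remaining": remaining,
                        "d1": state.d1,
                        "d2": state.d2,
                        "status1": state.status1.value,
                        "status2": state.status2.value,
                        "ev_goal1": float(q1),
                        "ev_goal2": float(q2),
                        "optimal_action": self.action(state, remaining).value,
                    }
                )
        return pd.DataFrame(rows)


def backward_induction(spec: TaskSpec, exact: bool = False) -> ValuePolicyTable:
    """Solve the two-goal MDP exactly from the horizon backwards.

    Terminal values equal the attained-goal count; each earlier slice
    records both action values and the maximizing action. With
    ``exact=True`` the recursion runs in rational arithmetic and ties are
    detected by exact equality.
    """
    states = enumerate_states(spec)
    term = {
        s: (Fraction(terminal_value(s, spec.frame)) if exact else float(terminal_value(s, spec.frame)))
        for s in states
    }
    v: list[dict[JointState, Number]] = [term]
    q: list[dict[JointState, tuple[Number, Number]]] = [{}]
    for _ in range(1, spec.horizon + 1):
        v_next = v[-1]
        q_slice: dict[JointState, tuple[Number, Number]] = {}
        v_slice: dict[JointState, Number] = {}
        for s in states:
            e1 = expected_value(s, Action.GOAL1, v_next, spec, exact=exact)
            e2 = expected_value(s, Action.GOAL2, v_next, spec, exact=exact)
            q_slice[s] = (e1, e2)
            v_slice[s] = e1 if e1 >= e2 else e2
        q.append(q_slice)
        v.append(v_slice)
    return ValuePolicyTable(spec, q, v, exact)


class AttainmentProbs(NamedTuple):
    """Probability of attaining both, exactly one, or neither goal."""

    p_both: float
    p_one: float
    p_none: float


def _policy_actions(table: ValuePolicyTable, state: JointState, remaining: int) -> list[Action]:
    a = table.action(state, remaining)
    if a is Action.TIE:
        return [Action.GOAL1, Action.GOAL2]
    return [a]


def attainment_probabilities(
    spec: TaskSpec,
    table: ValuePolicyTable | None = None,
) -> AttainmentProbs:
    """Forward pass: goal-attainment probabilities under the (optimal) policy.

    Propagates the start-state distribution through the horizon following
    the policy in ``table`` (solved fresh if omitted); EV ties split
    probability equally between the two actions. Satisfies
    ``2 * p_both + p_one == v(start)`` under the optimal policy.
    """
    if table is None:
        table = backward_induction(spec)
    exact = table.exact
    one: Number = Fraction(1) if exact else 1.0
    dist: dict[JointState, Number] = {spec.start_state: one}
    for remaining in range(spec.horizon, 0, -1):
        nxt: dict[JointState, Number] = {}
        for state, pr in dist.items():
            if state.both_resolved:
                nxt[state] = nxt.get(state, one * 0) + pr
                continue
            actions = _policy_actions(table, state, remaining)
            share = pr / len(actions)
            for a in actions:
                for succ, tp in transition_distribution(state, a, spec, exact=exact).items():
                    nxt[succ] = nxt.get(succ, one * 0) + share * tp
        dist = nxt
    counts = [one * 0, one * 0, one * 0]
    for state, pr in dist.items():
        counts[terminal_value(state, spec.frame)] += pr
    return AttainmentProbs(float(counts[2]), float(counts[1]), float(counts[0]))
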