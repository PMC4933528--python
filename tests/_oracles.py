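"""Independent reference computations used to check the solver.

These deliberately avoid the package's dynamic-programming recursion:
state counts come from a plain cross product, expected values from
exhaustive enumeration of outcome paths, and attainment probabilities
either from that enumeration or from explicit transition matrices.
Only usable at small horizons/distances.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

from goalpursuit.mdp import (
    Action,
    GoalFrame,
    JointState,
    TaskSpec,
    ValuePolicyTable,
    terminal_value,
)


def brute_force_states(spec: TaskSpec) -> set[tuple[int, int]]:
    """Cross product of per-goal positions (d down to 0)."""
    return set(
        itertools.product(range(spec.d_start[0] + 1), range(spec.d_start[1] + 1))
    )


def _step_prob(spec: TaskSpec, prioritized: bool) -> Fraction:
    p = spec.p_prioritized if prioritized else spec.p_nonprioritized
    return 1 - p if spec.frame is GoalFrame.AVOIDANCE else p


def _policy_actions(table: ValuePolicyTable, state: JointState, remaining: int):
    if state.both_resolved:
        return [Action.GOAL1]  # action irrelevant, absorbing
    a = table.action(state, remaining)
    return [Action.GOAL1, Action.GOAL2] if a is Action.TIE else [a]


def path_enumeration_outcomes(
    spec: TaskSpec, table: ValuePolicyTable
) -> dict[int, Fraction]:
    """Exact distribution of the attained-goal count under the table's policy.

    Recursively enumerates every outcome path, splitting EV ties 1/2-1/2.
    Exponential in the horizon; keep T small.
    """

    def recurse(d1: int, d2: int, remaining: int) -> dict[int, Fraction]:
        state = JointState.make(spec.frame, d1, d2)
        if remaining == 0:
            return {terminal_value(state, spec.frame): Fraction(1)}
        out: dict[int, Fraction] = {}
        actions = _policy_actions(table, state, remaining)
        share = Fraction(1, len(actions))
        for action in actions:
            p1 = _step_prob(spec, action is Action.GOAL1) if d1 > 0 else Fraction(0)
            p2 = _step_prob(spec, action is Action.GOAL2) if d2 > 0 else Fraction(0)
            for s1 in (0, 1):
                for s2 in (0, 1):
                    pr = (p1 if s1 else 1 - p1) * (p2 if s2 else 1 - p2)
                    if pr == 0:
                        continue
                    for k, q in recurse(d1 - s1, d2 - s2, remaining - 1).items():
                        out[k] = out.get(k, Fraction(0)) + share * pr * q
        return out

    return recurse(spec.d_start[0], spec.d_start[1], spec.horizon)


def path_enumeration_value(spec: TaskSpec, table: ValuePolicyTable) -> Fraction:
    """Expected attained goals from the start, by exhaustive path enumeration."""
    dist = path_enumeration_outcomes(spec, table)
    return sum(Fraction(k) * p for k, p in dist.items())


def matrix_attainment(spec: TaskSpec, table: ValuePolicyTable) -> tuple[float, float, float]:
    """(p_both, p_one, p_none) by explicit stochastic-matrix propagation.

    Builds, for each stage, the full state-transition matrix implied by the
    policy (ties split 1/2-1/2) and multiplies it into the start
    distribution; resolved pairs are absorbing rows.
    """
    states = sorted(
        ((a, b) for a in range(spec.d_start[0] + 1) for b in range(spec.d_start[1] + 1))
    )
    index = {s: i for i, s in enumerate(states)}
    n = len(states)

    def stage_matrix(remaining: int) -> np.ndarray:
        m = np.zeros((n, n))
        for (d1, d2), i in index.items():
            state = JointState.make(spec.frame, d1, d2)
            if state.both_resolved:
                m[i, i] = 1.0
                continue
            actions = _policy_actions(table, state, remaining)
            for action in actions:
                p1 = float(_step_prob(spec, action is Action.GOAL1)) if d1 > 0 else 0.0
                p2 = float(_step_prob(spec, action is Action.GOAL2)) if d2 > 0 else 0.0
                for s1 in (0, 1):
                    for s2 in (0, 1):
                        pr = (p1 if s1 else 1 - p1) * (p2 if s2 else 1 - p2)
                        if pr == 0:
                            continue
                        m[i, index[(d1 - s1, d2 - s2)]] += pr / len(actions)
        return m

    dist = np.zeros(n)
    dist[index[spec.d_start]] = 1.0
    for remaining in range(spec.horizon, 0, -1):
        dist = dist @ stage_matrix(remaining)
    probs = [0.0, 0.0, 0.0]
    for (d1, d2), i in index.items():
        k = terminal_value(JointState.make(spec.frame, d1, d2), spec.frame)
        probs[k] += dist[i]
    return probs[2], probs[1], probs[0]
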