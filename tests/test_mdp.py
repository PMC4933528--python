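"""Solver tests: state space, transitions, backward induction, forward pass."""

from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from goalpursuit import (
    Action,
    BothGoalsResolvedError,
    GoalFrame,
    JointState,
    TaskSpec,
    attainment_probabilities,
    backward_induction,
    enumerate_states,
    expected_value,
    terminal_value,
    transition_distribution,
)

from _oracles import brute_force_states, path_enumeration_outcomes, path_enumeration_value


def small_specs():
    """Hypothesis strategy over small, exhaustively checkable tasks."""
    return st.builds(
        TaskSpec,
        frame=st.sampled_from([GoalFrame.APPROACH, GoalFrame.AVOIDANCE]),
        horizon=st.integers(1, 5),
        d_start=st.tuples(st.integers(0, 4), st.integers(0, 4)),
        p_prioritized=st.sampled_from([Fraction(4, 5), Fraction(1, 2), Fraction(9, 10)]),
        p_nonprioritized=st.sampled_from([Fraction(1, 5), Fraction(3, 10), Fraction(0)]),
    )


class TestStateSpace:
    def test_two_four_level_projects_have_16_states(self, consultant_spec):
        assert len(enumerate_states(consultant_spec)) == 16

    @pytest.mark.parametrize(
        "d_start, expected",
        [((1, 1), 4), ((3, 2), 12), ((0, 0), 1), ((4, 0), 5)],
    )
    def test_state_count_is_cross_product(self, d_start, expected):
        spec = TaskSpec("approach", 3, d_start)
        states = enumerate_states(spec)
        assert len(states) == expected
        assert {(s.d1, s.d2) for s in states} == brute_force_states(spec)

    def test_terminal_values_partition_16_states(self, consultant_spec):
        counts = Counter(
            terminal_value(s, consultant_spec.frame)
            for s in enumerate_states(consultant_spec)
        )
        assert counts == {2: 1, 1: 6, 0: 9}

    def test_avoidance_pending_counts_as_attained(self):
        state = JointState.make("avoidance", 2, 0)
        assert terminal_value(state, "avoidance") == 1
        assert terminal_value(JointState.make("avoidance", 3, 1), "avoidance") == 2


class TestTransitions:
    def test_approach_bernoulli_product(self):
        spec = TaskSpec("approach", 1, (1, 1))
        state = spec.start_state
        dist = transition_distribution(state, Action.GOAL1, spec)
        by_d = {(s.d1, s.d2): p for s, p in dist.items()}
        assert by_d == {
            (0, 0): Fraction(4, 25),
            (0, 1): Fraction(16, 25),
            (1, 0): Fraction(1, 25),
            (1, 1): Fraction(4, 25),
        }

    def test_degenerate_probabilities_single_successor(self):
        spec = TaskSpec("approach", 1, (2, 2), 1.0, 0.0)
        dist = transition_distribution(spec.start_state, Action.GOAL1, spec)
        assert len(dist) == 1
        ((succ, p),) = dist.items()
        assert (succ.d1, succ.d2) == (1, 2) and p == 1

    def test_avoidance_prioritized_goal_loses_with_complement_probability(self):
        spec = TaskSpec("avoidance", 1, (1, 5))
        dist = transition_distribution(spec.start_state, Action.GOAL1, spec)
        p_goal1_fails = sum(p for s, p in dist.items() if s.d1 == 0)
        assert p_goal1_fails == Fraction(1, 5)
        p_goal2_loses = sum(p for s, p in dist.items() if s.d2 == 4)
        assert p_goal2_loses == Fraction(4, 5)

    def test_no_decision_when_both_goals_resolved(self):
        spec = TaskSpec("approach", 1, (1, 1))
        with pytest.raises(BothGoalsResolvedError):
            transition_distribution(JointState.make("approach", 0, 0), Action.GOAL1, spec)

    def test_resolved_goal_is_frozen(self):
        spec = TaskSpec("approach", 1, (1, 1))
        state = JointState.make("approach", 0, 1)
        dist = transition_distribution(state, Action.GOAL2, spec)
        assert all(s.d1 == 0 for s in dist)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(spec=small_specs())
    def test_transition_probabilities_sum_to_one(self, spec):
        for state in enumerate_states(spec):
            if state.both_resolved:
                continue
            for action in (Action.GOAL1, Action.GOAL2):
                dist = transition_distribution(state, action, spec)
                assert sum(dist.values()) == 1


class TestBackwardInduction:
    def test_consultant_week10_expected_values(self, consultant_spec, consultant_table):
        """One week left; project A needs the report, B analysis and report."""
        state = JointState.make("approach", 1, 2)
        e_a, e_b = consultant_table.q(state, 1)
        assert e_a == Fraction(4, 5)
        assert e_b == Fraction(3, 10)
        assert consultant_table.action(state, 1) is Action.GOAL1

    def test_expected_value_matches_table(self, consultant_spec, consultant_table):
        state = JointState.make("approach", 1, 2)
        v0 = {s: Fraction(terminal_value(s, "approach")) for s in enumerate_states(consultant_spec)}
        assert expected_value(state, Action.GOAL1, v0, consultant_spec) == Fraction(4, 5)
        assert expected_value(state, Action.GOAL2, v0, consultant_spec) == Fraction(3, 10)

    def test_absorbing_state_value_is_two(self, consultant_spec, consultant_table):
        both_done = JointState.make("approach", 0, 0)
        for remaining in (1, 5, 10):
            assert consultant_table.v(both_done, remaining) == 2

    def test_symmetric_states_tie_at_every_stage(self, consultant_table):
        for remaining in range(1, 11):
            for d in (1, 2, 3):
                state = JointState.make("approach", d, d)
                assert consultant_table.action(state, remaining) is Action.TIE

    def test_values_bounded_by_goal_count(self, consultant_table):
        for remaining in range(0, 11):
            for state in consultant_table.states():
                assert 0 <= consultant_table.v(state, remaining) <= 2

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(spec=small_specs())
    def test_dp_value_matches_exhaustive_path_enumeration(self, spec):
        """v(start) equals the path-enumeration expectation, in exact arithmetic."""
        table = backward_induction(spec, exact=True)
        assert table.start_value() == path_enumeration_value(spec, table)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(spec=small_specs())
    def test_float_and_exact_solvers_agree(self, spec):
        exact = backward_induction(spec, exact=True)
        approx = backward_induction(spec, exact=False)
        for state in exact.states():
            for remaining in range(1, spec.horizon + 1):
                qe = exact.q(state, remaining)
                qf = approx.q(state, remaining)
                assert abs(float(qe[0]) - qf[0]) < 1e-9
                assert abs(float(qe[1]) - qf[1]) < 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(spec=small_specs())
    def test_dominance_being_closer_never_hurts(self, spec):
        """Decreasing one pending goal's distance never lowers the state value."""
        table = backward_induction(spec, exact=True)
        for state in table.states():
            if state.d1 >= 1:
                closer = JointState.make(spec.frame, state.d1 - 1, state.d2)
                for remaining in range(0, spec.horizon + 1):
                    if spec.frame is GoalFrame.APPROACH:
                        assert table.v(closer, remaining) >= table.v(state, remaining)
                    else:
                        # avoidance: a smaller buffer is worse
                        assert table.v(closer, remaining) <= table.v(state, remaining)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(spec=small_specs())
    def test_horizon_monotonicity(self, spec):
        """More stages help approach goals and hurt avoidance goals."""
        longer = TaskSpec(spec.frame, spec.horizon + 1, spec.d_start,
                          spec.p_prioritized, spec.p_nonprioritized)
        table = backward_induction(longer, exact=True)
        start = longer.start_state
        v_short, v_long = table.v(start, spec.horizon), table.v(start, spec.horizon + 1)
        if spec.frame is GoalFrame.APPROACH:
            assert v_long >= v_short
        else:
            assert v_long <= v_short


class TestForwardPass:
    def test_already_resolved_start(self):
        spec = TaskSpec("approach", 2, (0, 0))
        probs = attainment_probabilities(spec)
        assert probs.p_both == 1.0

    def test_single_stage_bernoulli_product(self):
        spec = TaskSpec("approach", 1, (1, 1))
        probs = attainment_probabilities(spec)
        assert probs == pytest.approx((0.16, 0.68, 0.16))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(spec=small_specs())
    def test_expected_goals_identity(self, spec):
        """2 p_both + p_one equals the optimal start value."""
        table = backward_induction(spec)
        probs = attainment_probabilities(spec, table)
        assert probs.p_both + probs.p_one + probs.p_none == pytest.approx(1.0, abs=1e-12)
        assert 2 * probs.p_both + probs.p_one == pytest.approx(
            table.start_value(), abs=1e-9
        )

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(spec=small_specs())
    def test_forward_pass_matches_path_enumeration(self, spec):
        table = backward_induction(spec, exact=True)
        probs = attainment_probabilities(spec, table)
        dist = path_enumeration_outcomes(spec, table)
        assert probs.p_both == pytest.approx(float(dist.get(2, 0)), abs=1e-12)
        assert probs.p_one == pytest.approx(float(dist.get(1, 0)), abs=1e-12)


def _policy_value(spec, chooser) -> float:
    """Expected attained goals under a fixed stationary policy.

    ``chooser(state) -> list of actions`` (several = equal split).
    """
    from goalpursuit.mdp import transition_distribution as trans

    states = enumerate_states(spec)
    v = {s: float(terminal_value(s, spec.frame)) for s in states}
    for _ in range(spec.horizon):
        nv = {}
        for s in states:
            if s.both_resolved:
                nv[s] = v[s]
                continue
            actions = chooser(s)
            total = 0.0
            for a in actions:
                total += sum(p * v[succ] for succ, p in trans(s, a, spec, exact=False).items())
            nv[s] = total / len(actions)
        v = nv
    return v[spec.start_state]


def test_optimal_policy_beats_heuristics():
    """DP value >= always-better, always-worse and uniform-random policies."""
    rng = np.random.default_rng(20240917)

    def worse_goal_actions(spec, s):
        if s.d1 == s.d2:
            return [Action.GOAL1, Action.GOAL2]
        farther = Action.GOAL1 if s.d1 > s.d2 else Action.GOAL2
        nearer = Action.GOAL2 if farther is Action.GOAL1 else Action.GOAL1
        if s.status1.value != "pending":
            return [Action.GOAL2]
        if s.status2.value != "pending":
            return [Action.GOAL1]
        return [farther] if spec.frame is GoalFrame.APPROACH else [nearer]

    for _ in range(50):
        spec = TaskSpec(
            frame=rng.choice(["approach", "avoidance"]),
            horizon=int(rng.integers(1, 7)),
            d_start=(int(rng.integers(0, 5)), int(rng.integers(0, 5))),
        )
        v_opt = backward_induction(spec).start_value()
        heuristics = [
            lambda s: worse_goal_actions(spec, s),
            lambda s: [a for a in [Action.GOAL1, Action.GOAL2] if a not in worse_goal_actions(spec, s)] or worse_goal_actions(spec, s),
            lambda s: [Action.GOAL1, Action.GOAL2],
        ]
        for chooser in heuristics:
            assert v_opt >= _policy_value(spec, chooser) - 1e-9


def test_tidy_table_export(consultant_table):
    df = consultant_table.to_frame()
    assert list(df.columns) == [
        "stage", "remaining", "d1", "d2", "status1", "status2",
        "ev_goal1", "ev_goal2", "optimal_action",
    ]
    assert len(df) == 16 * 10
    week10 = df[(df.remaining == 1) & (df.d1 == 1) & (df.d2 == 2)].iloc[0]
    assert week10.ev_goal1 == 0.8 and week10.ev_goal2 == 0.3
    assert week10.optimal_action == "goal1"
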