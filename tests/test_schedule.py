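"""Schedule state machines: DRL scoring, adjusting DRL, progressive ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drltiming import (
    InvalidInputError,
    InvalidParameterError,
    ScheduleConfig,
    ScheduleKind,
    reinforcers_to_reach,
    run_adjusting_drl,
    run_progressive_ratio,
    score_drl_session,
)

increasing_times = st.lists(
    st.floats(min_value=0.01, max_value=1800, allow_nan=False), min_size=0, max_size=60
).map(lambda xs: np.unique(np.asarray(xs)))


class TestScoreDrl:
    @pytest.mark.parametrize(
        "times, criterion, expected_flags, expected_reinf",
        [
            ([16, 40, 45], 15, [True, True, False], 2),
            ([], 15, [], 0),
            ([1, 2, 3], 15, [False, False, False], 0),
        ],
    )
    def test_examples(self, times, criterion, expected_flags, expected_reinf):
        flags, n, r = score_drl_session(times, criterion)
        assert flags.tolist() == expected_flags
        assert n == len(times)
        assert r == expected_reinf

    def test_first_response_measured_from_session_start(self):
        flags, _, _ = score_drl_session([10.0], 15)
        assert flags.tolist() == [False]
        flags, _, _ = score_drl_session([20.0], 15)
        assert flags.tolist() == [True]

    def test_strict_inequality_at_criterion(self):
        flags, _, _ = score_drl_session([15.0, 30.0], 15)
        assert flags.tolist() == [False, False]

    @pytest.mark.parametrize("times", [[3, 2, 5], [-1, 4], [1, 1, 2]])
    def test_invalid_times_rejected(self, times):
        with pytest.raises(InvalidInputError):
            score_drl_session(times, 15)

    @given(increasing_times)
    @settings(derandomize=True, max_examples=50)
    def test_zero_criterion_reinforces_every_positive_irt(self, times):
        flags, n, r = score_drl_session(times, 0.0)
        assert r <= n
        assert r == int(np.sum(np.diff(times, prepend=0.0) > 0))

    @given(increasing_times, st.floats(0, 30), st.floats(0, 30))
    @settings(derandomize=True, max_examples=50)
    def test_raising_criterion_never_gains_reinforcers(self, times, c1, c2):
        lo, hi = sorted((c1, c2))
        _, _, r_lo = score_drl_session(times, lo)
        _, _, r_hi = score_drl_session(times, hi)
        assert r_hi <= r_lo


class TestAdjustingDrl:
    CFG = ScheduleConfig(kind=ScheduleKind.ADJUSTING_DRL, criterion_s=15.0)

    def test_single_reinforced_response_increments(self):
        res = run_adjusting_drl([3.0], self.CFG)
        assert res.reinforced_flags.tolist() == [True]
        assert res.final_criterion_s == pytest.approx(2 * 1.0075)

    def test_no_reinforcement_leaves_criterion(self):
        res = run_adjusting_drl([1.0, 2.0, 3.0], self.CFG)
        assert not res.reinforced_flags.any()
        assert res.final_criterion_s == 2.0

    def test_reaches_target_on_270th_reinforced_response(self):
        # one reinforced response every 16 s: every response is reinforced
        # until the criterion saturates at 15
        times = np.arange(1, 400) * 16.0
        res = run_adjusting_drl(times, self.CFG)
        below = np.nonzero(res.criterion_trajectory < 15.0)[0]
        # criterion in force first reaches 15 for the response after the 270th
        assert below.size == 270
        assert res.final_criterion_s == 15.0

    @given(increasing_times)
    @settings(derandomize=True, max_examples=50)
    def test_trajectory_monotone_and_capped(self, times):
        res = run_adjusting_drl(times, self.CFG)
        traj = res.criterion_trajectory
        assert np.all(np.diff(traj) >= 0) if traj.size > 1 else True
        assert np.all(traj <= 15.0)
        assert res.final_criterion_s <= 15.0


class TestReinforcersToReach:
    @pytest.mark.parametrize(
        "start, target, frac, expected",
        [(2, 15, 0.0075, 270), (15, 15, 0.0075, 0), (2, 4, 1.0, 1)],
    )
    def test_examples(self, start, target, frac, expected):
        assert reinforcers_to_reach(start, target, frac) == expected

    def test_target_below_start_rejected(self):
        with pytest.raises(InvalidInputError):
            reinforcers_to_reach(15, 2, 0.0075)

    @given(
        st.floats(0.5, 10),
        st.floats(0, 20),
        st.floats(0.001, 0.5),
    )
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force_iteration(self, start, extra, frac):
        target = start + extra
        k = reinforcers_to_reach(start, target, frac)
        value, steps = start, 0
        while value < target:
            value *= 1.0 + frac
            steps += 1
        assert k == steps


class TestProgressiveRatio:
    CFG = ScheduleConfig(kind=ScheduleKind.PR, pr_progression=(1, 2, 3))

    def test_hand_traced_progression(self):
        res = run_progressive_ratio([1, 2, 3, 4, 5, 6], self.CFG)
        assert res.reinforcers_earned == 3
        assert res.breakpoint_ratio == 3
        assert res.total_responses == 6

    def test_empty_session(self):
        res = run_progressive_ratio([], self.CFG)
        assert res.reinforcers_earned == 0
        assert res.breakpoint_ratio == 0
        assert res.total_responses == 0

    def test_hang_limit_terminates_session(self):
        res = run_progressive_ratio([1.0, 950.0], self.CFG)
        assert res.total_responses == 1
        assert res.termination_time_s == pytest.approx(901.0)

    def test_hang_before_first_press(self):
        res = run_progressive_ratio([950.0], self.CFG)
        assert res.total_responses == 0

    def test_reinforcers_capped_by_progression(self):
        res = run_progressive_ratio(np.arange(1, 100, dtype=float), self.CFG)
        assert res.reinforcers_earned == 3

    @given(increasing_times)
    @settings(derandomize=True, max_examples=50)
    def test_cumulative_curve_non_decreasing_and_complete(self, times):
        res = run_progressive_ratio(times, self.CFG)
        curve = res.cumulative_curve
        assert np.all(np.diff(curve) >= 0) if curve.size > 1 else True
        assert curve[-1] == res.total_responses

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidParameterError):
            ScheduleConfig(kind=ScheduleKind.PR, pr_progression=(3, 2, 1))
        with pytest.raises(InvalidParameterError):
            ScheduleConfig(kind=ScheduleKind.DRL, criterion_s=-1)
        with pytest.raises(InvalidParameterError):
            ScheduleConfig(kind=ScheduleKind.ADJUSTING_DRL, increment_fraction=1.5)
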