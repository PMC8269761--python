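"""Distance-staircase state machine: transitions, termination, oracle equivalence."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acuitytrack.results import OUT_OF_RANGE, TestResult
from acuitytrack.scale import AcuityScale, grid_distances, grid_logmars
from acuitytrack.observer import Observer, PsychometricEye, step_observer
from acuitytrack.tracker import (
    StaircaseState,
    next_instruction,
    previous_result_start,
    record_response,
    run_tracker_test,
    start_test,
)

GRID = grid_distances()
LEVELS = grid_logmars()


def drive(pattern, start=30.0):
    """Feed a fixed response pattern to the state machine."""
    state = start_test(start_distance_cm=start)
    for correct in pattern:
        if state.finished:
            break
        record_response(state, correct)
    return state


# ---------------------------------------------------------------------------
# literal-prose simulator used as the independent oracle
# ---------------------------------------------------------------------------


def prose_simulator(responses):
    """Follow the written test procedure verbatim, on logMAR levels.

    Returns (finished, final_level_or_None, levels_consumed_so_far state)
    where final level None encodes "worse than the closest distance".
    Structured deliberately unlike the state machine: explicit while
    loops over an iterator of responses, levels as floats.
    """
    it = iter(responses)
    level = 1.0  # 30 cm start
    top, bottom = 0.0, 1.3

    def nxt():
        return next(it)

    try:
        # coarse: one letter per distance, move 3 lines farther on success
        while True:
            if nxt():
                if abs(level - top) < 1e-9:
                    return True, top
                level = max(top, round(level - 0.3, 10))
            else:
                break
        # first error: come one line closer, then 3-of-5 blocks
        level = min(bottom, round(level + 0.1, 10))
        while True:
            correct = incorrect = 0
            while correct < 3 and incorrect < 3:
                if nxt():
                    correct += 1
                else:
                    incorrect += 1
            if correct == 3:
                return True, level
            if abs(level - bottom) < 1e-9:
                return True, None
            level = round(level + 0.1, 10)
    except StopIteration:
        return False, level


class TestStartAndInstructions:
    def test_default_start_is_thirty_cm_coarse(self):
        state = start_test()
        assert state.phase == "coarse"
        assert state.current_distance_cm == pytest.approx(30.0)
        assert state.current_demand_logmar == pytest.approx(1.0)
        assert not state.finished

    def test_boundary_start_at_reference(self):
        state = start_test(start_distance_cm=300.0)
        assert state.grid_index == 0
        assert state.phase == "coarse"

    def test_off_grid_start_rejected_unless_snapped(self):
        with pytest.raises(ValueError):
            start_test(start_distance_cm=29.0)
        snapped = start_test(start_distance_cm=29.0, snap_start=True)
        assert snapped.current_distance_cm == pytest.approx(30.0)

    def test_next_instruction_reports_distance_and_letters_left(self):
        state = start_test()
        assert next_instruction(state) == (pytest.approx(30.0), 5)
        record_response(state, False)  # -> fine phase
        record_response(state, True)
        record_response(state, False)
        dist, remaining = next_instruction(state)
        assert remaining == 3

    def test_next_instruction_errors_when_finished(self):
        state = drive([True] * 10)  # walks to the ceiling
        assert state.finished
        with pytest.raises(ValueError):
            next_instruction(state)


class TestTransitions:
    def test_coarse_correct_moves_three_lines_farther(self):
        state = drive([True])
        assert state.phase == "coarse"
        assert state.current_demand_logmar == pytest.approx(0.7)
        assert state.current_distance_cm == pytest.approx(59.86, abs=0.01)

    def test_coarse_correct_at_ceiling_finishes_at_reference(self):
        state = drive([True, True, True, True])  # 1.0 -> .7 -> .4 -> .1 -> done? not yet
        assert not state.finished  # clamped to level 0, awaiting one more letter
        assert state.current_demand_logmar == pytest.approx(0.0)
        record_response(state, True)
        assert state.finished
        assert state.final_distance_cm == pytest.approx(300.0)
        assert state.measured_logmar == pytest.approx(0.0)

    def test_coarse_moves_clamp_at_ceiling(self):
        state = drive([True, True, True])  # from 1.0: 0.7, 0.4, then clamp 0.1->?
        assert state.current_demand_logmar == pytest.approx(0.1)
        record_response(state, True)
        assert state.current_demand_logmar == pytest.approx(0.0)

    def test_coarse_error_switches_to_fine_one_line_closer(self):
        state = drive([False])
        assert state.phase == "fine"
        assert state.current_demand_logmar == pytest.approx(1.1)
        assert state.trials_this_block == 0

    def test_fine_block_pass_on_three_straight(self):
        state = drive([False, True, True, True])
        assert state.finished
        assert state.measured_logmar == pytest.approx(1.1)

    def test_fine_block_fail_moves_one_line_closer(self):
        # I,C,I,I: three incorrect before three correct -> fail in 4 letters
        state = drive([False] + [False, True, False, False])
        assert not state.finished
        assert state.phase == "fine"
        assert state.current_demand_logmar == pytest.approx(1.2)
        assert state.trials_this_block == 0

    def test_floor_failure_scores_out_of_range(self):
        state = drive([False] + [False] * 9)
        assert state.finished
        assert state.final_distance_cm is None
        assert state.measured_logmar == OUT_OF_RANGE

    def test_response_after_finish_rejected(self):
        state = drive([False, True, True, True])
        with pytest.raises(ValueError):
            record_response(state, True)

    def test_trial_log_records_every_letter(self):
        pattern = [True, False, True, False, False, False]
        state = drive(pattern)
        assert [t.correct for t in state.trial_log] == pattern
        assert [t.trial for t in state.trial_log] == list(range(1, len(pattern) + 1))


class TestOracleEquivalence:
    def test_exhaustive_prose_equivalence_length_12(self):
        """State machine == literal-prose simulator on all 2^12 patterns."""
        for bits in itertools.product([True, False], repeat=12):
            state = drive(list(bits))
            oracle = prose_simulator(list(bits))
            assert state.finished == oracle[0], bits
            if state.finished:
                expected_level = oracle[1]
                if expected_level is None:
                    assert state.final_distance_cm is None, bits
                else:
                    assert state.measured_logmar == pytest.approx(
                        expected_level, abs=1e-9
                    ), bits
            else:
                assert state.current_demand_logmar == pytest.approx(
                    oracle[1], abs=1e-9
                ), bits

    @given(st.lists(st.booleans(), min_size=0, max_size=80))
    def test_termination_bound(self, pattern):
        state = drive(pattern + [False] * 80)  # force progress to an end
        assert state.finished
        assert len(state.trial_log) <= 5 + 5 * len(GRID)

    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    def test_grid_index_always_legal_and_score_on_grid(self, pattern):
        state = drive(pattern)
        assert 0 <= state.grid_index < len(GRID)
        if state.finished and state.final_distance_cm is not None:
            assert any(
                state.final_distance_cm == pytest.approx(d) for d in GRID
            )


class TestRunTrackerTest:
    def test_perfect_observer_reaches_reference(self, rng):
        eye = PsychometricEye(true_logmar=-5.0, slope_sigma=0.01, guess_rate=0.0,
                              lapse_rate=0.0)
        obs = Observer(right_eye=eye, left_eye=eye)
        result = run_tracker_test(obs, "right", rng=rng)
        assert result.measured_logmar == pytest.approx(0.0)
        assert result.final_distance_cm == pytest.approx(300.0)

    def test_blind_observer_hits_the_floor(self, rng):
        eye = PsychometricEye(true_logmar=50.0, slope_sigma=0.01, guess_rate=0.0,
                              lapse_rate=0.0)
        obs = Observer(right_eye=eye, left_eye=eye)
        result = run_tracker_test(obs, "right", rng=rng)
        assert result.out_of_range

    def test_step_observer_lands_on_its_threshold_line(self, rng):
        result = run_tracker_test(step_observer(0.7), "right", rng=rng)
        assert result.measured_logmar == pytest.approx(0.7)
        assert result.final_distance_cm == pytest.approx(59.86, abs=0.01)

    def test_reproducible_under_seed(self):
        eye = PsychometricEye(true_logmar=0.45)
        obs = Observer(right_eye=eye, left_eye=eye)
        a = run_tracker_test(obs, "right", rng=np.random.default_rng(42))
        b = run_tracker_test(obs, "right", rng=np.random.default_rng(42))
        assert a.measured_logmar == b.measured_logmar
        assert [t.correct for t in a.trial_log] == [t.correct for t in b.trial_log]


class TestPreviousResultStart:
    def test_passthrough_of_grid_score(self):
        prev = TestResult(protocol="tracker", eye="right", measured_logmar=0.4,
                          final_distance_cm=GRID[4])
        assert previous_result_start(prev) == pytest.approx(GRID[4])

    def test_out_of_range_falls_back_to_default(self):
        prev = TestResult(protocol="tracker", eye="right",
                          measured_logmar=math.inf, final_distance_cm=None)
        assert previous_result_start(prev) == 30.0

    def test_reference_distance_passthrough(self):
        prev = TestResult(protocol="tracker", eye="right", measured_logmar=0.0,
                          final_distance_cm=300.0)
        assert previous_result_start(prev) == 300.0


class TestSerialisation:
    def test_state_round_trips_through_dict(self):
        state = drive([True, False, True])
        clone = StaircaseState.from_dict(state.to_dict())
        assert clone.grid_index == state.grid_index
        assert clone.phase == state.phase
        assert clone.trial_log == state.trial_log
        record_response(clone, True)  # still driveable after resume
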