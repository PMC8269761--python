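"""Letter-size threshold protocol (single crowded letter, fixed distance).

The chart shows one crowded letter per logMAR size line, 0.7 down to 0.0
by default.  Procedure:

1. DESCEND: one letter per line from the largest size until an error
   (an error on the very first letter means acuity is worse than the
   chart ceiling — out-of-range sentinel).
2. CONFIRM: return to the line above the error and present four more
   letters there (the earlier correct letter counts as one of five).
3. A line passing 3-of-5 sends testing down to the next smaller line
   with five fresh letters; testing continues downward until a line
   scores below 3/5.
4. The score is the deepest (smallest) line holding a >=3/5 block,
   rounded to whole lines — matching how such scores are analysed.
   If the first confirmation block fails, testing moves back *up* one
   line at a time (each of those lines already holds one correct letter
   from the descent) until a line passes; failing even the top line
   scores out-of-range.

Blocks stop early once three correct or three incorrect letters decide
the outcome, so no line ever needs more than five letters.  Viewing
distance is fixed and calibrated, so a letter on line ``v`` simply has
demand ``v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observer import Observer, draw_session_jitter, respond
from .results import OUT_OF_RANGE, TestResult, TrialRecord

__all__ = [
    "ChartState",
    "start_chart",
    "chart_record_response",
    "line_score",
    "run_isight_test",
    "descend_screen",
    "DEFAULT_START_LINE",
    "DEFAULT_MIN_LINE",
]

DEFAULT_START_LINE = 0.7
DEFAULT_MIN_LINE = 0.0

_BLOCK_SIZE = 5
_PASS_MARK = 3


def _make_lines(start_line: float, min_line: float, step: float = 0.1) -> list[float]:
    """Chart lines, largest (easiest) first."""
    n = int(round((start_line - min_line) / step)) + 1
    return [round(start_line - k * step, 10) for k in range(n)]


def line_score(trials_on_line: list[bool]) -> bool:
    """Pass/fail of one line: at least 3 of (up to) 5 letters correct."""
    if not 1 <= len(trials_on_line) <= _BLOCK_SIZE:
        raise ValueError("a line holds between 1 and 5 letter responses")
    return sum(bool(t) for t in trials_on_line) >= _PASS_MARK


@dataclass
class ChartState:
    """State machine for the letter-size protocol (driveable trial by trial)."""

    lines: list[float]
    line_index: int = 0
    phase: str = "descend"  # "descend" | "confirm"
    line_correct: int = 0
    line_incorrect: int = 0
    finished: bool = False
    score_logmar: float | None = None
    trial_log: list[TrialRecord] = field(default_factory=list)
    # confirm-phase direction: None until the first block resolves,
    # then "down" (probing smaller lines) or "up" (recovering larger ones)
    confirm_dir: str | None = None
    # whether a line's correct descent letter counts toward its 5
    credit_descend_letter: bool = True

    @property
    def current_line(self) -> float:
        return self.lines[self.line_index]

    @property
    def measured_logmar(self) -> float:
        if not self.finished:
            raise ValueError("test not finished")
        return OUT_OF_RANGE if self.score_logmar is None else self.score_logmar


def start_chart(
    start_line: float = DEFAULT_START_LINE,
    min_line: float = DEFAULT_MIN_LINE,
    credit_descend_letter: bool = True,
) -> ChartState:
    """Fresh chart state.  ``credit_descend_letter=False`` makes every
    confirmation line use five fresh letters instead of counting the
    letter already answered correctly during the descent."""
    if start_line < min_line:
        raise ValueError("start_line must not be below min_line")
    return ChartState(
        lines=_make_lines(start_line, min_line),
        credit_descend_letter=credit_descend_letter,
    )


def chart_record_response(state: ChartState, correct: bool) -> ChartState:
    """Advance the chart protocol by one letter response (mutates state)."""
    if state.finished:
        raise ValueError("cannot record a response on a finished test")
    state.trial_log.append(
        TrialRecord(
            trial=len(state.trial_log) + 1,
            phase=state.phase,
            distance_cm=None,
            demand_logmar=state.current_line,
            correct=bool(correct),
        )
    )
    last = len(state.lines) - 1

    if state.phase == "descend":
        if correct:
            if state.line_index == last:
                # every line read on descent: confirm the smallest line,
                # crediting the letter just answered
                state.phase = "confirm"
                state.line_correct = 1 if state.credit_descend_letter else 0
                state.line_incorrect = 0
            else:
                state.line_index += 1
        else:
            if state.line_index == 0:
                state.finished = True
                state.score_logmar = None  # worse than the chart ceiling
            else:
                # back to the line above; its descent letter counts as 1/5
                state.phase = "confirm"
                state.line_index -= 1
                state.line_correct = 1 if state.credit_descend_letter else 0
                state.line_incorrect = 0
        return state

    # confirm phase
    if correct:
        state.line_correct += 1
    else:
        state.line_incorrect += 1
    if state.line_correct == _PASS_MARK:
        _confirm_block_done(state, passed=True)
    elif state.line_incorrect == _PASS_MARK:
        _confirm_block_done(state, passed=False)
    return state


def _confirm_block_done(state: ChartState, passed: bool) -> None:
    last = len(state.lines) - 1
    if passed:
        if state.confirm_dir == "up" or state.line_index == last:
            # recovered line (or chart floor) is the deepest pass
            state.finished = True
            state.score_logmar = state.current_line
        else:
            state.confirm_dir = "down"
            state.line_index += 1
            state.line_correct = 0  # fresh five letters on the smaller line
            state.line_incorrect = 0
    else:
        if state.confirm_dir == "down":
            # the line above passed on the way down: that is the score
            state.finished = True
            state.score_logmar = state.lines[state.line_index - 1]
        elif state.line_index == 0:
            state.finished = True
            state.score_logmar = None  # even the top line failed
        else:
            state.confirm_dir = "up"
            state.line_index -= 1
            # descent letter on this line was correct
            state.line_correct = 1 if state.credit_descend_letter else 0
            state.line_incorrect = 0


def run_isight_test(
    observer: Observer,
    eye_side: str,
    rng: np.random.Generator | None = None,
    start_line: float = DEFAULT_START_LINE,
    min_line: float = DEFAULT_MIN_LINE,
    credit_descend_letter: bool = True,
) -> TestResult:
    """Run a full letter-size threshold test for one eye.

    Session jitter (filter inhomogeneity) is drawn once per test.
    """
    rng = np.random.default_rng(observer.rng_seed) if rng is None else rng
    jitter = draw_session_jitter(observer, eye_side, rng)
    state = start_chart(start_line, min_line, credit_descend_letter)
    while not state.finished:
        correct = respond(
            observer, eye_side, state.current_line, rng, session_jitter=jitter
        )
        chart_record_response(state, correct)
    return TestResult(
        protocol="isight",
        eye=eye_side,
        measured_logmar=state.measured_logmar,
        final_distance_cm=None,
        trial_log=state.trial_log,
    )


def descend_screen(
    observer: Observer,
    eye_side: str,
    rng: np.random.Generator,
    start_line: float = DEFAULT_START_LINE,
    min_line: float = DEFAULT_MIN_LINE,
    session_jitter: float = 0.0,
) -> float:
    """Coarse screening measure: the descend phase only.

    One letter per line from ``start_line`` downward; the last correctly
    read line is the screening vision.  An error on the first letter
    returns the out-of-range sentinel.  Not a threshold measure — used to
    choose occlusion foils.
    """
    lines = _make_lines(start_line, min_line)
    last_correct: float | None = None
    for line in lines:
        if respond(observer, eye_side, line, rng, session_jitter=session_jitter):
            last_correct = line
        else:
            break
    return OUT_OF_RANGE if last_correct is None else last_correct
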