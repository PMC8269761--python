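"""Distance-staircase acuity protocol (fixed letter, variable distance).

The tester holds the phone at app-specified distances on the logarithmic
grid (15-300 cm, one grid step = one 0.1 logMAR line).  The test starts
at 30 cm (1.0 logMAR demand) in a COARSE phase showing one letter per
distance: each correct answer moves the phone three lines farther
(harder); the first error switches to a FINE phase that moves one line
closer at a time, presenting up to five letters per distance with
three-out-of-five as the pass mark.  The first passed block ends the
test; its distance is the score, converted back to logMAR for analysis.

Edge behaviour (documented choices where the procedure is silent):

* a coarse correct at the 300 cm ceiling ends the test at 0.0 logMAR;
* three-line coarse moves clamp at the ceiling rather than reflect;
* a coarse error at the closest grid level starts the fine phase at that
  same level (there is nowhere closer to go);
* failing the block at the closest level scores "worse than 1.3"
  (:data:`~acuitytrack.results.OUT_OF_RANGE`), not 1.3 itself, so
  floored scores can be excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observer import Observer, draw_session_jitter, respond
from .results import OUT_OF_RANGE, TestResult, TrialRecord
from .scale import AcuityScale, DEFAULT_SCALE, distance_to_logmar, grid_distances, grid_logmars

__all__ = [
    "StaircaseState",
    "start_test",
    "next_instruction",
    "record_response",
    "run_tracker_test",
    "previous_result_start",
    "COARSE_STEP_LINES",
    "DEFAULT_START_DISTANCE_CM",
]

#: Coarse-phase move after a correct answer, in lines ("three up").
COARSE_STEP_LINES = 3
DEFAULT_START_DISTANCE_CM = 30.0

_BLOCK_SIZE = 5
_PASS_MARK = 3


@dataclass
class StaircaseState:
    """Full state of a distance-staircase test in progress.

    ``grid_index`` 0 is the farthest distance (reference demand, hardest);
    the last index is the closest (largest demand, easiest).
    JSON-serialisable via :meth:`to_dict` / :meth:`from_dict` for
    pause/resume.
    """

    scale: AcuityScale
    grid_index: int
    phase: str = "coarse"  # "coarse" | "fine"
    block_correct: int = 0
    block_incorrect: int = 0
    finished: bool = False
    final_distance_cm: float | None = None
    trial_log: list[TrialRecord] = field(default_factory=list)

    # Grid caches derived from the scale (not part of identity/state).
    def __post_init__(self) -> None:
        self._levels = grid_logmars(self.scale)
        self._distances = grid_distances(self.scale)
        if not 0 <= self.grid_index < len(self._distances):
            raise ValueError("grid_index outside the distance grid")

    @property
    def trials_this_block(self) -> int:
        return self.block_correct + self.block_incorrect

    @property
    def current_distance_cm(self) -> float:
        return self._distances[self.grid_index]

    @property
    def current_demand_logmar(self) -> float:
        return self._levels[self.grid_index]

    @property
    def measured_logmar(self) -> float:
        """Score in logMAR; out-of-range sentinel below the grid floor."""
        if not self.finished:
            raise ValueError("test not finished")
        if self.final_distance_cm is None:
            return OUT_OF_RANGE
        return distance_to_logmar(self.final_distance_cm, self.scale)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["scale"] = asdict(self.scale)
        d["trial_log"] = [asdict(t) for t in self.trial_log]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StaircaseState":
        d = dict(d)
        d["scale"] = AcuityScale(**d["scale"])
        d["trial_log"] = [TrialRecord(**t) for t in d["trial_log"]]
        return cls(**d)


def start_test(
    scale: AcuityScale = DEFAULT_SCALE,
    start_distance_cm: float = DEFAULT_START_DISTANCE_CM,
    snap_start: bool = False,
) -> StaircaseState:
    """Fresh coarse-phase state at ``start_distance_cm`` (default 30 cm).

    The start must lie on the distance grid; with ``snap_start`` an
    off-grid start is snapped to the nearest grid distance instead of
    raising.
    """
    distances = grid_distances(scale)
    diffs = [abs(d - start_distance_cm) for d in distances]
    idx = int(np.argmin(diffs))
    if diffs[idx] > 1e-6 * max(1.0, start_distance_cm) and not snap_start:
        raise ValueError(
            f"start distance {start_distance_cm} cm is not on the grid; "
            "pass snap_start=True to snap to the nearest level"
        )
    return StaircaseState(scale=scale, grid_index=idx)


def next_instruction(state: StaircaseState) -> tuple[float, int]:
    """(distance to hold the phone at, letters remaining in the block)."""
    if state.finished:
        raise ValueError("test already finished")
    return state.current_distance_cm, _BLOCK_SIZE - state.trials_this_block


def record_response(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one letter response (mutates ``state``)."""
    if state.finished:
        raise ValueError("cannot record a response on a finished test")
    state.trial_log.append(
        TrialRecord(
            trial=len(state.trial_log) + 1,
            phase=state.phase,
            distance_cm=state.current_distance_cm,
            demand_logmar=state.current_demand_logmar,
            correct=bool(correct),
        )
    )
    last = len(state._distances) - 1

    if state.phase == "coarse":
        if correct:
            if state.grid_index == 0:
                state.finished = True
                state.final_distance_cm = state._distances[0]
            else:
                state.grid_index = max(0, state.grid_index - COARSE_STEP_LINES)
        else:
            state.phase = "fine"
            state.grid_index = min(last, state.grid_index + 1)
            state.block_correct = 0
            state.block_incorrect = 0
        return state

    # fine phase: 3-of-5 blocks, one line closer after each failed block
    if correct:
        state.block_correct += 1
    else:
        state.block_incorrect += 1
    if state.block_correct == _PASS_MARK:
        state.finished = True
        state.final_distance_cm = state.current_distance_cm
    elif state.block_incorrect == _PASS_MARK:
        if state.grid_index == last:
            state.finished = True
            state.final_distance_cm = None  # worse than the grid floor
        else:
            state.grid_index += 1
            state.block_correct = 0
            state.block_incorrect = 0
    return state


def run_tracker_test(
    observer: Observer,
    eye_side: str,
    scale: AcuityScale = DEFAULT_SCALE,
    rng: np.random.Generator | None = None,
    start_distance_cm: float = DEFAULT_START_DISTANCE_CM,
) -> TestResult:
    """Run a full staircase test for one eye of a synthetic observer.

    The filter-inhomogeneity jitter is drawn once at the start (one test
    = one session) and held fixed across all trials of the test.
    """
    rng = np.random.default_rng(observer.rng_seed) if rng is None else rng
    jitter = draw_session_jitter(observer, eye_side, rng)
    state = start_test(scale, start_distance_cm)
    while not state.finished:
        demand = state.current_demand_logmar
        correct = respond(observer, eye_side, demand, rng, session_jitter=jitter)
        record_response(state, correct)
    return TestResult(
        protocol="tracker",
        eye=eye_side,
        measured_logmar=state.measured_logmar,
        final_distance_cm=state.final_distance_cm,
        trial_log=state.trial_log,
    )


def previous_result_start(
    previous: TestResult, scale: AcuityScale = DEFAULT_SCALE
) -> float:
    """Start distance for a repeat test, based on the previous score.

    The previous final distance (clamped to the grid); an out-of-range
    previous result falls back to the default 30 cm start.
    """
    if previous.final_distance_cm is None or previous.out_of_range:
        return DEFAULT_START_DISTANCE_CM
    distances = grid_distances(scale)
    idx = int(np.argmin([abs(d - previous.final_distance_cm) for d in distances]))
    return distances[idx]
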