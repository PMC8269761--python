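"""Shared result containers for the two test protocols."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Sentinel measured logMAR for a score outside the instrument's range
#: (worse than the tracker floor of 1.3 or the chart ceiling of 0.7).
#: +inf keeps the "larger = worse" ordering and is easy to exclude.
OUT_OF_RANGE = math.inf


def is_out_of_range(logmar: float) -> bool:
    """True for the out-of-range sentinel score."""
    return math.isinf(logmar)


@dataclass(frozen=True)
class TrialRecord:
    """One presented letter: where/what was shown and the response."""

    trial: int
    phase: str
    distance_cm: float | None
    demand_logmar: float
    correct: bool


@dataclass
class TestResult:
    """Outcome of one monocular acuity test.

    ``final_distance_cm`` is populated by the distance-staircase protocol
    only; the letter-size protocol tests at a fixed viewing distance and
    leaves it ``None``.  ``measured_logmar`` is :data:`OUT_OF_RANGE` when
    the subject fell outside the instrument's measurable range.
    """

    __test__ = False  # despite the name, not a pytest class

    protocol: str
    eye: str
    measured_logmar: float
    final_distance_cm: float | None = None
    trial_log: list[TrialRecord] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trial_log)

    @property
    def out_of_range(self) -> bool:
        return is_out_of_range(self.measured_logmar)
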