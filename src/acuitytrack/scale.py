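"""Viewing-distance geometry for a fixed-size optotype.

A letter of fixed physical size subtends a visual angle inversely
proportional to viewing distance, so moving the phone away makes the task
harder.  With a reference pairing (300 cm <-> 0.0 logMAR by default) the
acuity *demand* of the letter at distance ``d`` is

    v(d) = v_ref + log10(d_ref / d)        [logMAR]

Demand is expressed on the logMAR size scale: a larger demand means a
larger apparent letter, i.e. an easier task.  One chart "line" is a
``line_step`` of 0.1 logMAR, which corresponds to a fixed *ratio* of
distances (10**0.1 ~ 1.259), hence the legal test distances form a
logarithmic grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AcuityScale",
    "DEFAULT_SCALE",
    "distance_to_logmar",
    "logmar_to_distance",
    "one_line_distance_reduction",
    "grid_logmars",
    "grid_distances",
    "optotype_physical_height",
]


@dataclass(frozen=True)
class AcuityScale:
    """Fixed-optotype distance scale.

    Parameters
    ----------
    reference_distance_cm : float
        Distance at which the letter's demand equals ``reference_logmar``
        (default 300 cm, the farthest legal test distance).
    reference_logmar : float
        Demand at the reference distance (default 0.0 logMAR, the best
        score the fixed letter size can certify).
    min_distance_cm, max_distance_cm : float
        Legal test range.  The nearest grid point may sit marginally
        outside ``min_distance_cm`` (15.04 cm vs the displayed "15 cm");
        it is treated as inside the range — the printed bound is the
        rounded display of that grid point.
    line_step : float
        One chart line in logMAR (default 0.1).
    """

    reference_distance_cm: float = 300.0
    reference_logmar: float = 0.0
    min_distance_cm: float = 15.0
    max_distance_cm: float = 300.0
    line_step: float = 0.1

    def __post_init__(self) -> None:
        if self.reference_distance_cm <= 0:
            raise ValueError("reference_distance_cm must be positive")
        if self.min_distance_cm <= 0 or self.max_distance_cm <= 0:
            raise ValueError("distance bounds must be positive")
        if self.min_distance_cm > self.max_distance_cm:
            raise ValueError("min_distance_cm must not exceed max_distance_cm")
        if self.line_step < 0:
            raise ValueError("line_step must be non-negative")


DEFAULT_SCALE = AcuityScale()


def distance_to_logmar(distance_cm: float, scale: AcuityScale = DEFAULT_SCALE) -> float:
    """Continuous logMAR demand of the fixed optotype at ``distance_cm``.

    Strictly decreasing in distance; not snapped to the line grid.
    """
    if distance_cm <= 0:
        raise ValueError(f"distance must be positive, got {distance_cm}")
    return scale.reference_logmar + math.log10(scale.reference_distance_cm / distance_cm)


def logmar_to_distance(logmar: float, scale: AcuityScale = DEFAULT_SCALE) -> float:
    """Distance (cm) at which the fixed optotype has demand ``logmar``.

    Exact inverse of :func:`distance_to_logmar`.
    """
    # Division form keeps round grid points exact (300 / 10**1.0 == 30.0).
    return scale.reference_distance_cm * 10.0**scale.reference_logmar / 10.0**logmar


def one_line_distance_reduction(distance_cm: float, scale: AcuityScale = DEFAULT_SCALE) -> float:
    """Reduction in test distance that raises demand by exactly one line.

    Because lines are log-spaced this is a fixed *fraction* of the current
    distance, ``d * (1 - 10**-line_step)`` — about 20.6 % for 0.1 logMAR
    lines (8.2 cm at 40 cm, 61.7 cm at 300 cm).
    """
    if distance_cm <= 0:
        raise ValueError(f"distance must be positive, got {distance_cm}")
    return distance_cm * (1.0 - 10.0 ** (-scale.line_step))


def grid_logmars(scale: AcuityScale = DEFAULT_SCALE) -> list[float]:
    """Legal demand levels: reference_logmar, +1 line, ... within the range.

    Levels are included while they do not exceed the demand at the nearest
    legal distance (within 1e-9); for the defaults this is the 14-level
    0.0–1.3 logMAR grid.
    """
    worst = distance_to_logmar(scale.min_distance_cm, scale)
    if scale.line_step == 0:
        return [scale.reference_logmar]
    levels = []
    k = 0
    while True:
        v = scale.reference_logmar + k * scale.line_step
        if v > worst + 1e-9:
            break
        levels.append(v)
        k += 1
    return levels


def grid_distances(scale: AcuityScale = DEFAULT_SCALE) -> list[float]:
    """Grid distances, sorted descending (farthest/hardest first)."""
    return [logmar_to_distance(v, scale) for v in grid_logmars(scale)]


def optotype_physical_height(scale: AcuityScale = DEFAULT_SCALE) -> float:
    """Physical height (mm) of a standard 5-arcmin optotype at reference.

    A letter whose strokes resolve at the reference demand subtends
    5 arcmin overall at the reference distance, giving a height of
    ``2 * d_ref * tan(2.5')`` — about 4.36 mm for the 300 cm / 0.0 logMAR
    default.  This render size is implied by the scale, not configured.
    """
    half_angle = math.radians(2.5 / 60.0)
    return 2.0 * scale.reference_distance_cm * 10.0 * math.tan(half_angle)
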