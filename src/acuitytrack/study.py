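"""End-to-end synthetic agreement study.

Replicates the repeated-measures design on a simulated cohort: screen
each subject with a descending single-letter screen while searching the
occlusion-foil ladder for blur that puts the better eye in the
[screening_floor, screening_ceiling] window with an interocular
difference of at least ``min_iad``; then test both eyes with both
protocols, twice each, in per-subject randomised order; finally apply
the exclusion rules and emit a tidy long-format results table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import isight, tracker
from .observer import CohortSpec, EYES, Observer
from .results import is_out_of_range
from .scale import AcuityScale, DEFAULT_SCALE

__all__ = ["StudyConfig", "ScreeningRecord", "screen_and_fit_filters", "run_study"]

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "subject_id",
    "eye",
    "app",
    "test_rep",
    "measured_logmar",
    "final_distance_cm",
    "excluded",
    "exclusion_reason",
]


@dataclass(frozen=True)
class StudyConfig:
    """Design parameters of the synthetic agreement study."""

    n_subjects: int = 36
    screening_floor: float = 0.2  # better eye must screen at least this blurred
    screening_ceiling: float = 0.7  # both eyes must stay measurable on the chart
    min_iad: float = 0.2  # at least two lines between the eyes
    repetitions: int = 2
    seed: int = 0
    randomize_app_order: bool = True
    randomize_eye_order: bool = True
    cohort: CohortSpec = field(default_factory=CohortSpec)
    scale: AcuityScale = DEFAULT_SCALE
    start_distance_cm: float = tracker.DEFAULT_START_DISTANCE_CM
    chart_start_line: float = isight.DEFAULT_START_LINE
    chart_min_line: float = isight.DEFAULT_MIN_LINE
    exclude_isight_better_than: float = 0.0
    use_previous_start: bool = True

    def __post_init__(self) -> None:
        if self.screening_floor >= self.screening_ceiling:
            raise ValueError("screening_floor must be below screening_ceiling")
        if self.repetitions < 1:
            raise ValueError("repetitions must be at least 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")


@dataclass
class ScreeningRecord:
    """Outcome of the foil-fitting screen for one subject."""

    subject_id: int | None
    right_label: str | None
    left_label: str | None
    right_screened: float | None
    left_screened: float | None
    unscreenable: bool


def _screen_ok(s_right: float, s_left: float, config: StudyConfig) -> bool:
    if is_out_of_range(s_right) or is_out_of_range(s_left):
        return False
    if s_right > config.screening_ceiling or s_left > config.screening_ceiling:
        return False
    better = min(s_right, s_left)
    if better < config.screening_floor:
        return False
    return abs(s_right - s_left) >= config.min_iad - 1e-9


def screen_and_fit_filters(
    observer: Observer,
    config: StudyConfig,
    rng: np.random.Generator,
) -> tuple[Observer, ScreeningRecord]:
    """Greedy foil-ladder search with a descending single-letter screen.

    Candidate foils per eye run from none through weakest to strongest;
    the first combination whose screening visions satisfy the study
    window wins.  Subjects with no satisfying combination come back
    flagged ``unscreenable`` (and are excluded downstream).
    """
    ladder_r = config.cohort.filter_ladder(rng)
    ladder_l = config.cohort.filter_ladder(rng)
    options_r = [None] + [ladder_r[lab] for lab in ladder_r]
    options_l = [None] + [ladder_l[lab] for lab in ladder_l]

    # Randomise which eye is pushed worse: the outer loop (weakest first)
    # runs over the designated better eye, so laterality stays balanced
    # across the cohort instead of one eye always taking the denser foil.
    right_is_better = bool(rng.random() < 0.5)
    if right_is_better:
        combos = itertools.product(options_r, options_l)
    else:
        combos = (
            (fr, fl) for fl, fr in itertools.product(options_l, options_r)
        )

    for filt_r, filt_l in combos:
        candidate = observer.with_filters(filt_r, filt_l)
        screened = {}
        for side in EYES:
            from .observer import draw_session_jitter

            jit = draw_session_jitter(candidate, side, rng)
            screened[side] = isight.descend_screen(
                candidate,
                side,
                rng,
                start_line=config.chart_start_line,
                min_line=config.chart_min_line,
                session_jitter=jit,
            )
        if _screen_ok(screened["right"], screened["left"], config):
            rec = ScreeningRecord(
                subject_id=observer.subject_id,
                right_label=filt_r.density_label if filt_r else None,
                left_label=filt_l.density_label if filt_l else None,
                right_screened=screened["right"],
                left_screened=screened["left"],
                unscreenable=False,
            )
            log.info(
                "subject %s screened: RE %s (%s), LE %s (%s)",
                observer.subject_id,
                screened["right"],
                rec.right_label,
                screened["left"],
                rec.left_label,
            )
            return candidate, rec

    log.info("subject %s unscreenable", observer.subject_id)
    failed = observer.with_filters(None, None)
    failed.unscreenable = True
    return failed, ScreeningRecord(
        subject_id=observer.subject_id,
        right_label=None,
        left_label=None,
        right_screened=None,
        left_screened=None,
        unscreenable=True,
    )


def _subject_orders(
    config: StudyConfig, rng: np.random.Generator
) -> tuple[tuple[str, str], tuple[str, str]]:
    apps = ("isight", "tracker")
    eyes = EYES
    if config.randomize_app_order and rng.random() < 0.5:
        apps = apps[::-1]
    if config.randomize_eye_order and rng.random() < 0.5:
        eyes = eyes[::-1]
    return apps, eyes


def run_study(config: StudyConfig | None = None) -> pd.DataFrame:
    """Run the full synthetic study; returns the tidy results table.

    One row per (subject, eye, app, repetition).  Subject-level exclusion
    flags mark (a) unscreenable subjects and (b) any letter-chart score
    better than the exclusion bound (0.0 logMAR by default).  Individual
    out-of-range sentinel scores (inf) stay in the table and are dropped
    pairwise at analysis time.  Deterministic for a given config seed;
    screening records (list of dicts) are attached as
    ``df.attrs["screening"]``.
    """
    config = config or StudyConfig()
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    rows: list[dict] = []
    screening_rows: list[dict] = []

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        observer = config.cohort.draw_observer(rng, subject_id=i)
        observer, screen_rec = screen_and_fit_filters(observer, config, rng)
        screening_rows.append(screen_rec.__dict__)

        if screen_rec.unscreenable:
            for rep in range(1, config.repetitions + 1):
                for app in ("isight", "tracker"):
                    for eye in EYES:
                        rows.append(
                            dict(
                                subject_id=i,
                                eye=eye,
                                app=app,
                                test_rep=rep,
                                measured_logmar=np.nan,
                                final_distance_cm=np.nan,
                                excluded=True,
                                exclusion_reason="unscreenable",
                            )
                        )
            continue

        apps, eyes = _subject_orders(config, rng)
        subject_rows: list[dict] = []
        prev_tracker: dict[str, float] = {}
        for rep in range(1, config.repetitions + 1):
            for app in apps:
                for eye in eyes:
                    if app == "tracker":
                        start = prev_tracker.get(eye, config.start_distance_cm)
                        result = tracker.run_tracker_test(
                            observer,
                            eye,
                            scale=config.scale,
                            rng=rng,
                            start_distance_cm=start,
                        )
                        if config.use_previous_start:
                            prev_tracker[eye] = tracker.previous_result_start(
                                result, config.scale
                            )
                    else:
                        result = isight.run_isight_test(
                            observer,
                            eye,
                            rng=rng,
                            start_line=config.chart_start_line,
                            min_line=config.chart_min_line,
                        )
                    subject_rows.append(
                        dict(
                            subject_id=i,
                            eye=eye,
                            app=app,
                            test_rep=rep,
                            measured_logmar=result.measured_logmar,
                            final_distance_cm=result.final_distance_cm,
                            excluded=False,
                            exclusion_reason="",
                        )
                    )

        reason = _exclusion_reason(subject_rows, config)
        if reason:
            for r in subject_rows:
                r["excluded"] = True
                r["exclusion_reason"] = reason
        rows.extend(subject_rows)

    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    # plain records (not a frame): DataFrame-valued attrs break pandas ops
    df.attrs["screening"] = screening_rows
    return df


def _exclusion_reason(subject_rows: list[dict], config: StudyConfig) -> str:
    isight_scores = [
        r["measured_logmar"] for r in subject_rows if r["app"] == "isight"
    ]
    if any(
        s < config.exclude_isight_better_than - 1e-9
        for s in isight_scores
        if not is_out_of_range(s)
    ):
        return "isight_better_than_range"
    return ""
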