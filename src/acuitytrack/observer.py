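"""Synthetic psychophysical observers.

Each eye responds to a single-letter presentation through a standard
four-parameter psychometric function on the logMAR *demand* axis

    p(correct | demand v) = gamma + (1 - gamma - lambda) * F((v - t) / sigma)

with logistic F, threshold ``t`` (logMAR), spread ``sigma`` (logMAR),
guess rate ``gamma`` (1/6 for a six-letter forced choice) and lapse rate
``lambda``.  Larger demand means a larger apparent letter, so p rises
with demand.

Amblyopic blur is emulated by a Bangerter-style occlusion foil: a filter
adds a fixed ``blur_shift`` to the eye's threshold plus a per-session
jitter (``inhomogeneity_sd``) reflecting that real foils are not optically
homogeneous — the jitter is drawn once per test session, not per trial,
and is the main driver of test-retest variability beyond Bernoulli noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PsychometricEye",
    "BangerterFilter",
    "Observer",
    "CohortSpec",
    "FILTER_LABELS",
    "filter_label_value",
    "p_correct",
    "respond",
    "draw_session_jitter",
    "step_observer",
    "sample_cohort",
]

EYES = ("right", "left")

#: Bangerter foil ladder, weakest (least blur) to strongest.
FILTER_LABELS = ("1.0", "0.8", "0.6", "0.4", "0.3", "0.2", "0.1", "<0.1")


def filter_label_value(label: str) -> float:
    """Numeric reading of a foil's nominal density label ("<0.1" -> 0.05)."""
    return 0.05 if label == "<0.1" else float(label)


@dataclass(frozen=True)
class PsychometricEye:
    """Psychometric parameters of one eye (unfiltered)."""

    true_logmar: float
    slope_sigma: float = 0.05
    guess_rate: float = 1.0 / 6.0
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.slope_sigma <= 0:
            raise ValueError("slope_sigma must be positive")
        if self.guess_rate < 0 or self.lapse_rate < 0:
            raise ValueError("guess/lapse rates must be non-negative")
        if self.guess_rate + self.lapse_rate >= 1:
            raise ValueError("guess_rate + lapse_rate must be below 1")


@dataclass(frozen=True)
class BangerterFilter:
    """A graded occlusion foil degrading one eye's acuity.

    ``blur_shift`` is the logMAR decrement it adds to the eye's threshold;
    it need not (and in practice does not) match the nominal density
    label.  ``inhomogeneity_sd`` is the SD of the once-per-session
    threshold jitter caused by the foil's optical non-uniformity.
    """

    density_label: str
    blur_shift: float
    inhomogeneity_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.blur_shift < 0:
            raise ValueError("blur_shift must be non-negative")
        if self.inhomogeneity_sd < 0:
            raise ValueError("inhomogeneity_sd must be non-negative")


@dataclass
class Observer:
    """A synthetic participant: two eyes, optional filters, a seed."""

    right_eye: PsychometricEye
    left_eye: PsychometricEye
    right_filter: BangerterFilter | None = None
    left_filter: BangerterFilter | None = None
    rng_seed: int = 0
    subject_id: int | None = None
    unscreenable: bool = False

    def eye(self, side: str) -> PsychometricEye:
        if side == "right":
            return self.right_eye
        if side == "left":
            return self.left_eye
        raise ValueError(f"unknown eye side {side!r}")

    def filter(self, side: str) -> BangerterFilter | None:
        if side == "right":
            return self.right_filter
        if side == "left":
            return self.left_filter
        raise ValueError(f"unknown eye side {side!r}")

    def with_filters(
        self,
        right_filter: BangerterFilter | None,
        left_filter: BangerterFilter | None,
    ) -> "Observer":
        return replace(self, right_filter=right_filter, left_filter=left_filter)

    def effective_threshold(self, side: str, session_jitter: float = 0.0) -> float:
        """Eye threshold including filter blur and the session's jitter."""
        t = self.eye(side).true_logmar
        filt = self.filter(side)
        if filt is not None:
            t += filt.blur_shift + session_jitter
        return t


def p_correct(
    eye: PsychometricEye,
    demand_logmar: float,
    threshold: float | None = None,
) -> float:
    """Probability of a correct response at the given letter demand.

    ``threshold`` overrides the eye's bare ``true_logmar`` when filter
    blur / session jitter apply; monotone non-decreasing in demand,
    floored at the guess rate and capped at ``1 - lapse_rate``.
    """
    t = eye.true_logmar if threshold is None else threshold
    x = (demand_logmar - t) / eye.slope_sigma
    # logistic CDF, numerically symmetric
    if x >= 0:
        f = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        f = e / (1.0 + e)
    return eye.guess_rate + (1.0 - eye.guess_rate - eye.lapse_rate) * f


def respond(
    observer: Observer,
    eye_side: str,
    demand_logmar: float,
    rng: np.random.Generator,
    session_jitter: float = 0.0,
) -> bool:
    """One Bernoulli letter response; consumes exactly one uniform draw."""
    eye = observer.eye(eye_side)
    t = observer.effective_threshold(eye_side, session_jitter)
    return bool(rng.random() < p_correct(eye, demand_logmar, threshold=t))


def draw_session_jitter(
    observer: Observer, eye_side: str, rng: np.random.Generator
) -> float:
    """Draw the once-per-session filter-inhomogeneity jitter for one eye.

    Zero (consuming no randomness) for an unfiltered eye or a foil with
    zero inhomogeneity.
    """
    filt = observer.filter(eye_side)
    if filt is None or filt.inhomogeneity_sd == 0:
        return 0.0
    return float(rng.normal(0.0, filt.inhomogeneity_sd))


def step_observer(
    threshold: float,
    side: str = "right",
    other_threshold: float | None = None,
) -> Observer:
    """Deterministic step-function observer for hand-traceable tests.

    Reads every letter whose demand is >= ``threshold`` and nothing
    smaller (no guessing, no lapses).  Implemented as a near-degenerate
    logistic, with the true threshold nudged a hair below ``threshold`` so
    that a letter exactly at threshold is read correctly.
    """
    def eye(t: float) -> PsychometricEye:
        return PsychometricEye(
            true_logmar=t - 1e-6, slope_sigma=1e-9, guess_rate=0.0, lapse_rate=0.0
        )

    other = threshold if other_threshold is None else other_threshold
    if side == "right":
        return Observer(right_eye=eye(threshold), left_eye=eye(other))
    return Observer(right_eye=eye(other), left_eye=eye(threshold))


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of the synthetic study cohort.

    Defaults emulate the study population: healthy adults with baseline
    monocular acuity near -0.09 logMAR (RE -0.088 +/- 0.151, LE
    -0.089 +/- 0.170), subsequently blurred by foils into the 0.2-0.7
    logMAR testing window with an interocular difference of at least two
    lines.  The label->blur map is a documented stand-in (no published
    calibration exists): base blur 1.1 - label value, per-(subject, eye,
    label) jitter SD ``filter_jitter_sd``.
    """

    re_mean: float = -0.088
    re_sd: float = 0.151
    le_mean: float = -0.089
    le_sd: float = 0.170
    slope_sigma: float = 0.05
    guess_rate: float = 1.0 / 6.0
    lapse_rate: float = 0.01
    filter_jitter_sd: float = 0.1
    inhomogeneity_sd: float = 0.05

    def draw_observer(
        self, rng: np.random.Generator, subject_id: int | None = None
    ) -> Observer:
        """Sample one unfiltered observer from the cohort distributions."""
        re_t = float(rng.normal(self.re_mean, self.re_sd))
        le_t = float(rng.normal(self.le_mean, self.le_sd))
        mk = lambda t: PsychometricEye(  # noqa: E731
            true_logmar=t,
            slope_sigma=self.slope_sigma,
            guess_rate=self.guess_rate,
            lapse_rate=self.lapse_rate,
        )
        return Observer(
            right_eye=mk(re_t), left_eye=mk(le_t), subject_id=subject_id
        )

    def filter_ladder(
        self, rng: np.random.Generator
    ) -> dict[str, BangerterFilter]:
        """Per-eye foil set with subject-specific realised blur shifts."""
        ladder = {}
        for label in FILTER_LABELS:
            base = 1.1 - filter_label_value(label)
            blur = max(0.0, base + float(rng.normal(0.0, self.filter_jitter_sd)))
            ladder[label] = BangerterFilter(
                density_label=label,
                blur_shift=blur,
                inhomogeneity_sd=self.inhomogeneity_sd,
            )
        return ladder


def sample_cohort(
    spec: CohortSpec | None = None,
    n: int = 36,
    seed: int = 0,
    fit_filters: bool = True,
    study_config=None,
):
    """Draw ``n`` observers and (optionally) fit their occlusion foils.

    With ``fit_filters`` each observer is passed through the screening
    procedure (descending single-letter screen plus greedy foil-ladder
    search) so that the better eye screens within the study window and
    the interocular difference is at least two lines; observers for whom
    no foil combination works are flagged ``unscreenable``.  Deterministic
    for a given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    spec = spec or CohortSpec()
    children = np.random.SeedSequence(seed).spawn(n)
    observers = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        obs = spec.draw_observer(rng, subject_id=i)
        if fit_filters:
            from .study import StudyConfig, screen_and_fit_filters

            config = study_config or StudyConfig(cohort=spec)
            obs, _ = screen_and_fit_filters(obs, config, rng)
        observers.append(obs)
    return observers
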