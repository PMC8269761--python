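"""Method-agreement and test-retest statistics.

Implements the analysis surface of a two-method repeated-measures
agreement study on logMAR acuity scores: paired differences under an
explicit sign convention, Bland-Altman mean bias and 95 % limits of
agreement (bias +/- 1.96 * SD of the differences, sample SD with n-1),
two-sided paired t-tests, whole-line difference histograms with the
proportion within one line, and interocular acuity difference (IAD,
right minus left) summaries.

The module exposes both plain functions and a statsmodels-flavoured
model object: ``MethodAgreement(x, y).fit()`` returns an
:class:`AgreementResults` carrying the estimates with a ``summary()``
table and a Bland-Altman ``plot()``; :func:`assemble_tables` builds the
full study report (per-eye retest, cross-method, and IAD tables) from a
tidy results frame.

All internal arithmetic is unrounded; rounding to the 2-3 decimals used
in printed tables happens only in ``summary()`` / display helpers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .results import is_out_of_range

__all__ = [
    "CONVENTIONS",
    "paired_differences",
    "bland_altman",
    "loa_from_summary",
    "paired_t_test",
    "line_difference_distribution",
    "interocular_difference",
    "MethodAgreement",
    "AgreementResults",
    "assemble_tables",
    "StudyTables",
]

#: Multiplier defining the 95 % limits of agreement.
LOA_FACTOR = 1.96

#: Sign conventions: test-retest bias is first test minus second test;
#: cross-method bias is the letter-chart (isight) score minus the
#: distance-staircase (tracker) score.
CONVENTIONS = ("test1_minus_test2", "isight_minus_tracker")


def paired_differences(
    x: Sequence[float],
    y: Sequence[float],
    convention: str = "test1_minus_test2",
) -> np.ndarray:
    """Signed element-wise differences ``x - y`` under a named convention.

    ``x`` holds the first test (or the letter-chart scores) and ``y`` the
    second test (or the staircase scores); both conventions subtract
    ``y`` from ``x`` — the name records which measurement belongs where,
    so reports are unambiguous about the sign of the bias.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; use one of {CONVENTIONS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    return x - y


@dataclass(frozen=True)
class BlandAltman:
    mean_bias: float
    sd_diff: float
    upper_loa: float
    lower_loa: float


def bland_altman(diffs: Sequence[float]) -> BlandAltman:
    """Mean bias, SD of differences, and 95 % limits of agreement."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    upper, lower = loa_from_summary(bias, sd)
    return BlandAltman(bias, sd, upper, lower)


def loa_from_summary(mean_bias: float, sd_diff: float) -> tuple[float, float]:
    """Limits of agreement from a printed bias/SD pair: bias +/- 1.96 SD."""
    if sd_diff < 0:
        raise ValueError("sd_diff must be non-negative")
    return mean_bias + LOA_FACTOR * sd_diff, mean_bias - LOA_FACTOR * sd_diff


def paired_t_test(diffs: Sequence[float]) -> tuple[float, float]:
    """Two-sided one-sample t-test of the paired differences against 0.

    t = mean / (sd / sqrt(n)) with n-1 degrees of freedom.  Degenerate
    zero-variance input: p = 1 when the mean is also zero (no evidence of
    any difference), p -> 0 otherwise.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least two differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p


@dataclass(frozen=True)
class LineDifferenceSummary:
    """Whole-line binning of paired logMAR differences."""

    histogram: dict[int, int]
    n: int
    frac_within_one_line: float
    pct_within_one_line: int


def line_difference_distribution(
    diffs: Sequence[float], line_step: float = 0.1
) -> LineDifferenceSummary:
    """Histogram of signed whole-line differences and % within one line.

    Each difference maps to ``round(diff / line_step)`` lines using
    round-half-even (numpy's rint); halves cannot occur for whole-line
    protocol scores, so the tie rule only matters for letter-scored
    inputs.  The percentage is rounded to a whole percent as such
    proportions are conventionally reported.
    """
    d = np.asarray(diffs, dtype=float)
    lines = np.rint(d / line_step).astype(int)
    hist: dict[int, int] = {}
    for v in sorted(lines.tolist()):
        hist[v] = hist.get(v, 0) + 1
    frac = float(np.mean(np.abs(lines) <= 1)) if d.size else float("nan")
    pct = int(round(100.0 * frac)) if d.size else 0
    return LineDifferenceSummary(hist, int(d.size), frac, pct)


def interocular_difference(
    results: pd.DataFrame,
    app: str,
    test_rep: int,
    include_excluded: bool = False,
) -> tuple[pd.Series, tuple[float, float]]:
    """Per-subject IAD (right minus left) for one app/repetition.

    Returns the per-subject series (indexed by subject) and its
    (mean, sample SD).  Subjects missing either eye are dropped with a
    warning.
    """
    df = results[(results["app"] == app) & (results["test_rep"] == test_rep)]
    if not include_excluded:
        df = df[~df["excluded"]]
    df = _mask_out_of_range(df)
    wide = df.pivot_table(
        index="subject_id", columns="eye", values="measured_logmar", aggfunc="first"
    )
    missing = [c for c in ("right", "left") if c not in wide.columns]
    if missing:
        raise ValueError(f"no measurements for eye(s): {missing}")
    incomplete = wide.index[wide[["right", "left"]].isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) missing one eye: "
            f"{list(incomplete)}",
            stacklevel=2,
        )
        wide = wide.drop(index=incomplete)
    iad = wide["right"] - wide["left"]
    iad.name = f"iad_{app}_rep{test_rep}"
    return iad, (float(iad.mean()), float(iad.std(ddof=1)))


class MethodAgreement:
    """Agreement model for two paired measurement series.

    Parameters
    ----------
    x, y : array-like
        Paired scores (logMAR).  Under ``test1_minus_test2`` these are
        first and second administrations of the same method; under
        ``isight_minus_tracker`` the letter-chart and staircase scores.
    convention : str
        Sign convention for the differences (see :data:`CONVENTIONS`).
    line_step : float
        One chart line in logMAR, for the line-difference histogram.
    """

    def __init__(
        self,
        x: Sequence[float],
        y: Sequence[float],
        convention: str = "test1_minus_test2",
        line_step: float = 0.1,
    ) -> None:
        self.diffs = paired_differences(x, y, convention)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.convention = convention
        self.line_step = line_step

    @classmethod
    def from_dataframe(
        cls,
        results: pd.DataFrame,
        *,
        app: str | None = None,
        eye: str | None = None,
        reps: tuple[int, int] = (1, 2),
        apps: tuple[str, str] | None = None,
        test_rep: int | None = None,
        include_excluded: bool = False,
    ) -> "MethodAgreement":
        """Build a comparison from a tidy study results frame.

        Two modes: retest (``app`` + ``eye`` fixed, compares ``reps``)
        and cross-method (``apps`` + ``eye`` + ``test_rep`` fixed).
        """
        df = results if include_excluded else results[~results["excluded"]]
        df = _mask_out_of_range(df)
        if app is not None:
            sel = df[(df["app"] == app) & (df["eye"] == eye)]
            wide = sel.pivot_table(
                index="subject_id", columns="test_rep", values="measured_logmar"
            ).dropna()
            return cls(
                wide[reps[0]].to_numpy(),
                wide[reps[1]].to_numpy(),
                convention="test1_minus_test2",
            )
        if apps is None or test_rep is None:
            raise ValueError("provide either app+eye or apps+eye+test_rep")
        sel = df[(df["eye"] == eye) & (df["test_rep"] == test_rep)]
        wide = sel.pivot_table(
            index="subject_id", columns="app", values="measured_logmar"
        ).dropna()
        return cls(
            wide[apps[0]].to_numpy(),
            wide[apps[1]].to_numpy(),
            convention="isight_minus_tracker",
        )

    def fit(self) -> "AgreementResults":
        ba = bland_altman(self.diffs)
        t, p = paired_t_test(self.diffs)
        lines = line_difference_distribution(self.diffs, self.line_step)
        return AgreementResults(
            model=self,
            mean_bias=ba.mean_bias,
            sd_diff=ba.sd_diff,
            upper_loa=ba.upper_loa,
            lower_loa=ba.lower_loa,
            t_statistic=t,
            p_value=p,
            n=int(self.diffs.size),
            line_diff_histogram=lines.histogram,
            pct_within_one_line=lines.pct_within_one_line,
            frac_within_one_line=lines.frac_within_one_line,
        )


@dataclass
class AgreementResults:
    """Fitted agreement statistics for one paired comparison."""

    model: MethodAgreement
    mean_bias: float
    sd_diff: float
    upper_loa: float
    lower_loa: float
    t_statistic: float
    p_value: float
    n: int
    line_diff_histogram: dict[int, int]
    pct_within_one_line: int
    frac_within_one_line: float = field(default=float("nan"))

    def summary(self, decimals: int = 3) -> str:
        r = lambda v: f"{v:.{decimals}f}"  # noqa: E731
        lines = [
            "Paired agreement analysis",
            "=" * 41,
            f"convention        {self.model.convention}",
            f"n pairs           {self.n}",
            f"mean bias         {r(self.mean_bias)}",
            f"SD of differences {r(self.sd_diff)}",
            f"upper LoA         {r(self.upper_loa)}",
            f"lower LoA         {r(self.lower_loa)}",
            f"paired t          {self.t_statistic:.3f}",
            f"p value (2-sided) {self.p_value:.3f}",
            f"within one line   {self.pct_within_one_line}%",
            "=" * 41,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "convention": self.model.convention,
            "n": self.n,
            "mean_bias": self.mean_bias,
            "sd_diff": self.sd_diff,
            "upper_loa": self.upper_loa,
            "lower_loa": self.lower_loa,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "line_diff_histogram": {str(k): v for k, v in self.line_diff_histogram.items()},
            "pct_within_one_line": self.pct_within_one_line,
        }

    def plot(self, ax=None):
        """Bland-Altman plot: per-pair mean vs difference, bias and LoA."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        means = (self.model.x + self.model.y) / 2.0
        ax.scatter(means, self.model.diffs, alpha=0.6)
        for y, style in (
            (self.mean_bias, "-"),
            (self.upper_loa, "--"),
            (self.lower_loa, "--"),
        ):
            ax.axhline(y, linestyle=style, color="k", linewidth=1)
        ax.set_xlabel("Mean of pair (logMAR)")
        ax.set_ylabel(f"Difference ({self.model.convention}, logMAR)")
        return ax

    def plot_line_histogram(self, ax=None):
        """Bar chart of whole-line differences between the paired tests."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = sorted(self.line_diff_histogram)
        ax.bar(ks, [self.line_diff_histogram[k] for k in ks])
        ax.set_xlabel("Difference (lines)")
        ax.set_ylabel("Subjects")
        return ax


def _mask_out_of_range(results: pd.DataFrame) -> pd.DataFrame:
    """Sentinel (out-of-range) scores become NaN so pivots drop them pairwise."""
    df = results.copy()
    df.loc[np.isinf(df["measured_logmar"]), "measured_logmar"] = np.nan
    return df


def _usable(results: pd.DataFrame) -> pd.DataFrame:
    return _mask_out_of_range(results[~results["excluded"]])


@dataclass
class StudyTables:
    """Assembled study report: retest, cross-method, and IAD tables.

    ``retest`` — per app x eye: test-1/test-2 mean +/- SD, paired-t p,
    bias (test 1 - test 2) +/- SD, limits of agreement.
    ``cross_method`` — per eye x repetition: letter-chart minus staircase
    bias +/- SD, LoA, p.
    ``iad`` — per app: IAD (RE - LE) per repetition and the per-subject
    test-1 - test-2 IAD difference.  All values unrounded.
    """

    retest: pd.DataFrame
    cross_method: pd.DataFrame
    iad: pd.DataFrame
    n_subjects: int

    def summary(self, decimals: int = 3) -> str:
        parts = [
            f"Synthetic agreement study report (n = {self.n_subjects} analysed)",
            "",
            "Test-retest (bias = test 1 - test 2):",
            self.retest.round(decimals).to_string(),
            "",
            "Between methods (bias = letter chart - distance staircase):",
            self.cross_method.round(decimals).to_string(),
            "",
            "Interocular acuity difference (right - left):",
            self.iad.round(decimals).to_string(),
        ]
        return "\n".join(parts)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "retest": self.retest.reset_index().to_dict(orient="records"),
            "cross_method": self.cross_method.reset_index().to_dict(orient="records"),
            "iad": self.iad.reset_index().to_dict(orient="records"),
        }


def assemble_tables(results: pd.DataFrame) -> StudyTables:
    """Build the full study report from a tidy results frame.

    Requires at least two non-excluded subjects with complete data.
    """
    df = _usable(results)
    subjects = df["subject_id"].unique()
    if len(subjects) < 2:
        raise ValueError("need at least two non-excluded subjects")

    retest_rows = []
    for app in ("isight", "tracker"):
        for eye in ("right", "left"):
            m = MethodAgreement.from_dataframe(df, app=app, eye=eye)
            res = m.fit()
            retest_rows.append(
                {
                    "app": app,
                    "eye": eye,
                    "test1_mean": float(m.x.mean()),
                    "test1_sd": float(m.x.std(ddof=1)),
                    "test2_mean": float(m.y.mean()),
                    "test2_sd": float(m.y.std(ddof=1)),
                    "p_value": res.p_value,
                    "mean_bias": res.mean_bias,
                    "sd_diff": res.sd_diff,
                    "upper_loa": res.upper_loa,
                    "lower_loa": res.lower_loa,
                    "pct_within_one_line": res.pct_within_one_line,
                    "n": res.n,
                }
            )
    retest = pd.DataFrame(retest_rows).set_index(["app", "eye"])

    cross_rows = []
    for eye in ("right", "left"):
        for rep in (1, 2):
            res = MethodAgreement.from_dataframe(
                df, apps=("isight", "tracker"), eye=eye, test_rep=rep
            ).fit()
            cross_rows.append(
                {
                    "eye": eye,
                    "test_rep": rep,
                    "mean_bias": res.mean_bias,
                    "sd_diff": res.sd_diff,
                    "upper_loa": res.upper_loa,
                    "lower_loa": res.lower_loa,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
    cross_method = pd.DataFrame(cross_rows).set_index(["eye", "test_rep"])

    iad_rows = []
    for app in ("isight", "tracker"):
        iad1, (m1, s1) = interocular_difference(df, app, 1)
        iad2, (m2, s2) = interocular_difference(df, app, 2)
        joined = pd.concat([iad1, iad2], axis=1).dropna()
        diff = joined.iloc[:, 0] - joined.iloc[:, 1]
        t, p = paired_t_test(diff.to_numpy())
        iad_rows.append(
            {
                "app": app,
                "test1_mean": m1,
                "test1_sd": s1,
                "test2_mean": m2,
                "test2_sd": s2,
                "diff_mean": float(diff.mean()),
                "diff_sd": float(diff.std(ddof=1)),
                "p_value": p,
                "n": int(len(joined)),
            }
        )
    iad = pd.DataFrame(iad_rows).set_index("app")

    return StudyTables(
        retest=retest,
        cross_method=cross_method,
        iad=iad,
        n_subjects=int(len(subjects)),
    )
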