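"""Cohort comparison statistics: t-test, one-sided Fisher exact, chi-squared.

These are thin, opinionated wrappers around :mod:`scipy.stats` that return a
uniform :class:`TestResult` and enforce the conventions used throughout the
package: Welch's t by default, exact hypergeometric tails for Fisher, Pearson
chi-squared without continuity correction. No multiple-testing correction is
applied anywhere; callers running many tests in one report get a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "t_test", "fisher_one_sided", "chi_squared"]

# emit a note when a single report runs more than this many uncorrected tests
MANY_TESTS_NOTE_THRESHOLD = 20


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    group_means: tuple[float, ...] | None = None
    group_n: tuple[int, ...] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def t_test(x, y, flavor: str = "welch") -> TestResult:
    """Two-sided two-sample t-test.

    Parameters
    ----------
    x, y : array-like
        The two groups; each needs at least two finite values.
    flavor : {"welch", "pooled"}
        Welch (unequal variances) is the default; "pooled" uses the classic
        equal-variance statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if flavor not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test flavor: {flavor!r}")
    res = sps.ttest_ind(x, y, equal_var=(flavor == "pooled"))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        method=f"t-test ({flavor}, two-sided)",
        group_means=(float(x.mean()), float(y.mean())),
        group_n=(x.size, y.size),
    )


def fisher_one_sided(table, alternative: str = "less") -> TestResult:
    """One-sided Fisher exact test on a 2x2 table of counts.

    The p-value is the exact hypergeometric tail: for ``alternative="less"``
    the probability, under fixed margins, of a [0,0] cell at most as large as
    observed.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    if alternative not in ("less", "greater"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    odds, p = sps.fisher_exact(t, alternative=alternative)
    return TestResult(
        statistic=float(odds),
        p_value=float(p),
        method=f"Fisher exact (one-sided, {alternative})",
        group_n=(int(t[0].sum()), int(t[1].sum())),
        extra={"table": t.tolist()},
    )


def chi_squared(table) -> TestResult:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction; df = (r-1)(c-1); upper-tail p-value.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    stat, p, dof, expected = sps.chi2_contingency(t, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        df=float(dof),
        method="Pearson chi-squared (no continuity correction)",
        extra={"expected": np.asarray(expected).tolist()},
    )


def note_if_many_tests(n_tests: int) -> None:
    """Warn when a report runs many uncorrected tests."""
    if n_tests > MANY_TESTS_NOTE_THRESHOLD:
        warnings.warn(
            f"{n_tests} hypothesis tests run in one report with no "
            "multiple-testing correction; interpret p-values accordingly.",
            stacklevel=2,
        )
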