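"""Classical two-group statistics with the conventions fixed to match the
validation analysis: Mann-Whitney reported as min(U1, U2) with mid-rank ties,
normal approximation and 0.5 continuity correction; chi-squared on 2x2 tables
with Yates correction by default; Fisher's exact two-sided by the
probability-mass rule; Student's pooled t by default.

All heavy lifting is delegated to scipy.stats; this module pins the reporting
conventions and wraps results with their method metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with its p-value and method metadata."""

    statistic_name: str
    statistic_value: float
    p_value: float
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "value": self.statistic_value,
            "p": self.p_value,
            **self.details,
        }


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 count table with optional row/column labels."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2):
            raise ValueError("table must be 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("table must have at least one positive margin")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def _as_float_vec(x, name: str, min_len: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_len:
        raise UndefinedStatisticError(f"{name} needs at least {min_len} observations, got {arr.size}")
    if np.isnan(arr).any():
        raise UndefinedStatisticError(f"{name} input contains NaN")
    return arr


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with mid-rank ties.

    p is the two-sided t-approximation on n-2 degrees of freedom (adequate
    for cohort-sized samples); constant input is undefined.
    """
    xa = _as_float_vec(x, "spearman", 3)
    ya = _as_float_vec(y, "spearman", 3)
    if xa.size != ya.size:
        raise UndefinedStatisticError("spearman needs equal-length vectors")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(xa, ya)
    return TestResult("rho", float(rho), float(p), {"n": int(xa.size), "sidedness": "two-sided", "p_method": "t-approximation"})


def mann_whitney(x, y) -> TestResult:
    """Mann-Whitney U reported as min(U1, U2).

    Ties are handled with mid-ranks; p comes from the normal approximation
    with tie correction and a 0.5 continuity correction, two-sided. Both U
    statistics are kept in the details (U1 + U2 = n1*n2).
    """
    xa = _as_float_vec(x, "mann_whitney")
    ya = _as_float_vec(y, "mann_whitney")
    res = sps.mannwhitneyu(xa, ya, use_continuity=True, alternative="two-sided", method="asymptotic")
    u1 = float(res.statistic)
    u2 = xa.size * ya.size - u1
    return TestResult(
        "U",
        min(u1, u2),
        float(res.pvalue),
        {
            "U1": u1, "U2": u2, "n1": int(xa.size), "n2": int(ya.size),
            "tie_correction": True, "continuity_correction": True, "sidedness": "two-sided",
        },
    )


def fisher_2x2(table: ContingencyTable2x2) -> TestResult:
    """Fisher's exact test, two-sided by the probability-mass rule
    (sum of hypergeometric probabilities no larger than the observed
    table's, relative tolerance 1e-7)."""
    arr = table.as_array()
    res = sps.fisher_exact(arr, alternative="two-sided")
    odds = float(res.statistic) if np.isfinite(res.statistic) else float("inf")
    return TestResult("fisher_p", float(res.pvalue), float(res.pvalue),
                      {"odds_ratio": odds, "sidedness": "two-sided", "rule": "probability-mass"})


def chi2_2x2(table: ContingencyTable2x2, yates: bool = True) -> TestResult:
    """Chi-squared test of independence on a 2x2 table, Yates-corrected by
    default; a zero row or column margin leaves the test undefined."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("chi-squared undefined with a zero margin")
    res = sps.chi2_contingency(arr, correction=yates)
    return TestResult("chi2", float(res.statistic), float(res.pvalue),
                      {"df": int(res.dof), "yates": yates, "sidedness": "two-sided"})


def two_sample_t(x, y, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t-test, Student's pooled variance by default
    (``equal_var=False`` switches to Welch)."""
    xa = _as_float_vec(x, "t-test", 2)
    ya = _as_float_vec(y, "t-test", 2)
    if equal_var and np.ptp(np.concatenate([xa - xa.mean(), ya - ya.mean()])) == 0:
        raise UndefinedStatisticError("t-test undefined with zero pooled variance")
    res = sps.ttest_ind(xa, ya, equal_var=equal_var)
    variant = "student" if equal_var else "welch"
    return TestResult("t", float(res.statistic), float(res.pvalue),
                      {"variant": variant, "df": float(res.df), "sidedness": "two-sided"})


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (Royston approximation via scipy).

    Used as an advisory gate for parametric vs rank-based comparisons.
    """
    xa = _as_float_vec(x, "shapiro", 3)
    if xa.size > 5000:
        raise UndefinedStatisticError("shapiro-wilk supported for n <= 5000")
    if np.ptp(xa) == 0:
        raise UndefinedStatisticError("shapiro-wilk undefined for a constant vector")
    res = sps.shapiro(xa)
    return TestResult("W", float(res.statistic), float(res.pvalue), {"n": int(xa.size)})


def proportional_median_difference(
    median_a: float, median_b: float, observed_max: float, observed_min: float
) -> float:
    """|median_a - median_b| normalised by the observed score range.

    Returns a fraction in [0, 1] when the medians lie inside the range;
    multiply by 100 to report a percentage.
    """
    if not observed_max > observed_min:
        raise UndefinedStatisticError("observed range must be positive")
    return abs(median_a - median_b) / (observed_max - observed_min)
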