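"""The statistical toolkit used throughout the pore-pattern analyses.

Simple linear OLS with slope inference, Student's/Welch's t, Wilcoxon
rank-sum (exact for small tie-free samples, normal approximation with tie
correction otherwise), Shapiro–Wilk normality, and the manual-vs-automated
agreement analysis.  All p-values are two-sided; no multiple-testing
correction is applied anywhere.

``ols_fit`` is computed in closed form.  For simple regression the slope
t-test and the regression F-test are the same test, so a single p-value is
reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "TestResult",
    "AgreementReport",
    "ols_fit",
    "t_test",
    "wilcoxon_test",
    "shapiro_wilk",
    "manual_auto_agreement",
    "WILCOXON_EXACT_MAX_N",
]

#: Combined sample size at or below which the rank-sum test enumerates the
#: exact null distribution (ties always force the normal approximation).
WILCOXON_EXACT_MAX_N = 20


@dataclass
class RegressionResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    p_slope: float
    n: int
    resid_sd: float
    cov: np.ndarray  # 2x2 covariance of (slope, intercept)

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "r_squared": self.r_squared,
            "p_slope": self.p_slope,
            "n": self.n,
            "resid_sd": self.resid_sd,
            "cov": np.asarray(self.cov).tolist(),
        }


@dataclass
class TestResult:
    statistic: float
    p: float
    n1: int
    n2: int
    method: str

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p": self.p,
            "n1": self.n1,
            "n2": self.n2,
            "method": self.method,
        }


@dataclass
class AgreementReport:
    """Manual-vs-automated pore-count agreement for a set of specimens."""

    per_specimen_diff_pct: np.ndarray
    mean_diff_pct: float
    min_diff_pct: float
    max_diff_pct: float
    manual_mean_pd: float
    auto_mean_pd: float
    t_unpaired: "TestResult | None"  # None when n < 2
    t_paired: "TestResult | None"


def ols_fit(x, y) -> RegressionResult:
    """Simple linear ordinary least squares of y on x.

    Closed-form estimates; the slope p-value comes from the t distribution
    with n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx <= 0:
        raise ValueError("x is degenerate (zero variance)")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    ssr = float(np.sum(resid**2))
    sst = float(np.sum((y - ybar) ** 2))
    df = n - 2
    s2 = ssr / df if df > 0 else float("nan")
    slope_se = np.sqrt(s2 / sxx)
    intercept_se = np.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    cov = np.array(
        [[s2 / sxx, -s2 * xbar / sxx], [-s2 * xbar / sxx, s2 * (1.0 / n + xbar**2 / sxx)]]
    )
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    if slope_se > 0:
        tstat = slope / slope_se
        p = 2.0 * sps.t.sf(abs(tstat), df)
    else:
        p = 0.0 if slope != 0 else 1.0
    return RegressionResult(
        slope=slope,
        slope_se=float(slope_se),
        intercept=intercept,
        intercept_se=float(intercept_se),
        r_squared=float(r2),
        p_slope=float(p),
        n=n,
        resid_sd=float(np.sqrt(s2)),
        cov=cov,
    )


def t_test(a, b, variant: str = "student") -> TestResult:
    """Two-sided two-sample t test; ``student`` pools variance, ``welch``
    does not."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    method = "student_t" if variant == "student" else "welch_t"
    return TestResult(float(res.statistic), float(res.pvalue), a.size, b.size, method)


def wilcoxon_test(a, b, exact_max_n: int = WILCOXON_EXACT_MAX_N) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    The reported statistic W is the rank sum of the first group.  With
    combined n ≤ ``exact_max_n`` and no ties the exact permutation null is
    used; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    exact = (a.size + b.size) <= exact_max_n and not has_ties
    if exact:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "wilcoxon_exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "wilcoxon_normal"
    # scipy reports U1; convert to the rank-sum W of the first group
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return TestResult(w, float(min(res.pvalue, 1.0)), a.size, b.size, method)


def shapiro_wilk(x) -> TestResult:
    """Shapiro–Wilk normality test for 3 ≤ n ≤ 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(x)
    return TestResult(float(res.statistic), float(res.pvalue), x.size, 0, "shapiro_wilk")


def manual_auto_agreement(manual_counts, auto_counts, roi_areas) -> AgreementReport:
    """Agreement between manual and automated pore counting.

    Per-specimen relative difference is 100·|manual − auto| / manual (the
    manual count is the reference method).  The two mean pore densities are
    compared by an unpaired Student's t on the per-specimen PD vectors; a
    paired t is reported alongside since the specimens are matched.
    """
    manual = np.asarray(manual_counts, dtype=float)
    auto = np.asarray(auto_counts, dtype=float)
    areas = np.asarray(roi_areas, dtype=float)
    if not (manual.shape == auto.shape == areas.shape):
        raise ValueError("manual, auto and area vectors must have equal length")
    if np.any(manual <= 0):
        raise ValueError("manual counts must be positive (they are the denominator)")
    diff = 100.0 * np.abs(manual - auto) / manual
    pd_manual = manual / areas
    pd_auto = auto / areas
    if manual.size >= 2:
        t_unp = t_test(pd_manual, pd_auto, variant="student")
        tp = sps.ttest_rel(pd_manual, pd_auto)
        t_pair = TestResult(
            float(tp.statistic), float(tp.pvalue), manual.size, manual.size, "student_t_paired"
        )
    else:
        t_unp = t_pair = None
    return AgreementReport(
        per_specimen_diff_pct=diff,
        mean_diff_pct=float(diff.mean()),
        min_diff_pct=float(diff.min()),
        max_diff_pct=float(diff.max()),
        manual_mean_pd=float(pd_manual.mean()),
        auto_mean_pd=float(pd_auto.mean()),
        t_unpaired=t_unp,
        t_paired=t_pair,
    )
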