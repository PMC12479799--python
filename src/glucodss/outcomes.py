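"""Glycemic endpoint metrics and the trial's statistical procedures.

Time-in-range metrics use the consensus CGM bands (3.9-10 mmol/L target
range, with the tighter 3.9-7.8 band and the standard hypo-/hyperglycemia
thresholds), computed over historic sensor records only — user scans are
duplicate reads of the same signal.  The HbA1c surrogate is the glucose
management indicator (GMI), a published regression from mean sensor
glucose; it is an in-silico stand-in for the laboratory assay, never a
claim about it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import MGDL_PER_MMOLL, InvalidArgument
from .model import MINUTES_PER_DAY, CgmTrace

DAYTIME_START_H, DAYTIME_END_H = 7.0, 23.0

PERIODS = ("overall", "daytime", "overnight")


class EmptyMetrics(ValueError):
    """No sensor records remain after the period filter."""


@dataclass
class GlycemicMetrics:
    """Percent-of-time CGM metrics for one period."""

    period: str
    n_records: int
    mean_glucose: float  # mmol/L
    sd_glucose: float
    pct_3_9_to_10: float
    pct_3_9_to_7_8: float
    pct_below_3_9: float
    pct_below_3_0: float
    pct_above_7_8: float
    pct_above_10: float
    pct_above_13_9: float
    pct_above_16_7: float

    def as_dict(self) -> dict[str, float]:
        return {
            "period": self.period,
            "n_records": self.n_records,
            "mean_glucose": self.mean_glucose,
            "sd_glucose": self.sd_glucose,
            "tir_3.9_10": self.pct_3_9_to_10,
            "tir_3.9_7.8": self.pct_3_9_to_7_8,
            "below_3.9": self.pct_below_3_9,
            "below_3.0": self.pct_below_3_0,
            "above_7.8": self.pct_above_7_8,
            "above_10": self.pct_above_10,
            "above_13.9": self.pct_above_13_9,
            "above_16.7": self.pct_above_16_7,
        }


def _period_mask(times: np.ndarray, period: str) -> np.ndarray:
    tod_h = (times % MINUTES_PER_DAY) / 60.0
    if period == "overall":
        return np.ones(len(times), dtype=bool)
    if period == "daytime":
        return (tod_h >= DAYTIME_START_H) & (tod_h < DAYTIME_END_H)
    if period == "overnight":
        return (tod_h >= DAYTIME_END_H) | (tod_h < DAYTIME_START_H)
    raise InvalidArgument(f"unknown period {period!r}; expected one of {PERIODS}")


def cgm_metrics(trace: CgmTrace, period: str = "overall") -> GlycemicMetrics:
    """Time-in-range metrics over historic records in the given period.

    "In range" bands are closed intervals; "above"/"below" are strict, so
    the three bands <3.9 / 3.9-10 / >10 partition the records exactly.
    """
    hist = trace.historic()
    mask = _period_mask(hist.times, period)
    g = hist.glucose[mask]
    if len(g) == 0:
        raise EmptyMetrics(f"no historic records in period {period!r}")
    n = len(g)
    pct = lambda m: 100.0 * np.count_nonzero(m) / n  # noqa: E731
    return GlycemicMetrics(
        period=period,
        n_records=n,
        mean_glucose=float(g.mean()),
        sd_glucose=float(g.std(ddof=1)) if n > 1 else 0.0,
        pct_3_9_to_10=pct((g >= 3.9) & (g <= 10.0)),
        pct_3_9_to_7_8=pct((g >= 3.9) & (g <= 7.8)),
        pct_below_3_9=pct(g < 3.9),
        pct_below_3_0=pct(g < 3.0),
        pct_above_7_8=pct(g > 7.8),
        pct_above_10=pct(g > 10.0),
        pct_above_13_9=pct(g > 13.9),
        pct_above_16_7=pct(g > 16.7),
    )


def estimate_hba1c(mean_glucose: float) -> float:
    """Glucose management indicator (GMI), percent.

    GMI(%) = 3.31 + 0.02392 * mean glucose in mg/dL.
    """
    if mean_glucose <= 0:
        raise InvalidArgument("mean glucose must be > 0")
    return 3.31 + 0.02392 * mean_glucose * MGDL_PER_MMOLL


def treatment_effect(
    baseline: np.ndarray, final: np.ndarray, arm: np.ndarray
) -> tuple[float, tuple[float, float], float]:
    """Baseline-adjusted treatment effect on the change score (ANCOVA).

    With a single post-baseline measurement the mixed model of the trial's
    primary analysis reduces to OLS of (final - baseline) on arm plus the
    baseline value.  ``arm`` is 0 (control) / 1 (experimental).  Returns
    (effect, Wald 95% CI, two-sided p) for the arm coefficient.
    """
    import statsmodels.api as sm

    baseline = np.asarray(baseline, float)
    final = np.asarray(final, float)
    arm = np.asarray(arm, float)
    if len(baseline) != len(final) or len(baseline) != len(arm):
        raise InvalidArgument("baseline, final and arm must be the same length")
    for a in (0, 1):
        if np.count_nonzero(arm == a) < 2:
            raise InvalidArgument("need at least 2 subjects per arm")
    change = final - baseline
    X = sm.add_constant(np.column_stack([arm, baseline]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidArgument("degenerate design matrix")
    fit = sm.OLS(change, X).fit()
    effect = float(fit.params[1])
    ci = fit.conf_int(alpha=0.05)
    return effect, (float(ci[1][0]), float(ci[1][1])), float(fit.pvalues[1])


def proportion_test(
    k1: int, n1: int, k2: int, n2: int, method: str = "chi_squared"
) -> tuple[float, tuple[float, float], float]:
    """Two-sample proportion comparison.

    ``chi_squared`` is the pooled two-proportion chi-squared test without
    continuity correction (equal to the pooled z-test squared);
    ``fisher`` is the two-sided exact test summing hypergeometric tables
    with probability <= that observed.  The confidence interval on the
    difference p1 - p2 is Wald in both cases.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise InvalidArgument("group sizes must be > 0")
        if not 0 <= k <= n:
            raise InvalidArgument("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    diff = p1 - p2
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z = stats.norm.ppf(0.975)
    ci = (diff - z * se, diff + z * se)
    if method == "chi_squared":
        pooled = (k1 + k2) / (n1 + n2)
        if pooled in (0.0, 1.0):
            p = 1.0
        else:
            se0 = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            chi2 = (diff / se0) ** 2
            p = float(stats.chi2.sf(chi2, df=1))
    elif method == "fisher":
        _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
        p = float(p)
    else:
        raise InvalidArgument(f"unknown method {method!r}")
    return diff, ci, p


def sample_size_two_sample_t(
    sd: float, delta: float, power: float = 0.80, alpha: float = 0.05
) -> int:
    """Smallest per-arm n for a two-sided two-sample t-test.

    Iterates on the noncentral t distribution with 2n-2 degrees of
    freedom (the normal approximation under-counts by about one subject
    per arm at typical design values).
    """
    if sd <= 0 or delta <= 0:
        raise InvalidArgument("sd and delta must be > 0")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise InvalidArgument("power and alpha must be in (0, 1)")
    for n in range(2, 100_000):
        df = 2 * n - 2
        nc = delta / (sd * math.sqrt(2.0 / n))
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        achieved = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        if achieved >= power:
            return n
    raise RuntimeError("sample size search did not converge")


def two_group_compare(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Normality-gated two-group comparison.

    Shapiro-Wilk at alpha = 0.05 on each group selects the independent
    two-sample t-test (both normal) or the Wilcoxon rank-sum test.
    Returns (statistic, two-sided p, test name).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise InvalidArgument("need at least 3 observations per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        raise InvalidArgument("degenerate all-tied data")
    normal = (
        stats.shapiro(x).pvalue > 0.05 and stats.shapiro(y).pvalue > 0.05
        if (np.ptp(x) > 0 and np.ptp(y) > 0)
        else False
    )
    if normal:
        res = stats.ttest_ind(x, y)
        return float(res.statistic), float(res.pvalue), "t-test"
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), "rank-sum"
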