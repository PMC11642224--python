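"""Paired cohort comparison of the two pipeline arms.

Given per-subject area metrics from the attenuation arm and the intensity
arm, this module produces the standard reliability table: per-method mean,
SD, range and coefficient of variation (CV = 100 * SD / mean), the paired
mean difference with its t-based 95% confidence interval, a paired t-test,
and Wilcoxon's signed-rank test (two-sided).

The Wilcoxon p-value is exact for n <= 25 via the sign-flip permutation
distribution (dynamic programming over doubled midranks, so average ranks
for ties are handled exactly); larger samples use the normal approximation
with Var(W+) = sum(r_i^2) / 4, which absorbs the tie correction. Zero
differences are dropped before ranking (Wilcoxon's original treatment);
``zero_method="pratt"`` ranks them first and then drops them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError

EXACT_WILCOXON_MAX_N = 25


@dataclass
class MethodSummary:
    mean: float
    sd: float
    min: float
    max: float
    cv: float  # percent; NaN when mean == 0

    @classmethod
    def from_values(cls, values: np.ndarray) -> "MethodSummary":
        values = np.asarray(values, dtype=np.float64)
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        cv = 100.0 * sd / mean if mean != 0 else math.nan
        return cls(mean=mean, sd=sd, min=float(values.min()),
                   max=float(values.max()), cv=cv)


@dataclass
class PairedCohortResult:
    """Everything a reliability table reports for one paired comparison."""

    summary_a: MethodSummary
    summary_b: MethodSummary
    mean_difference: float
    se: float
    ci95: tuple[float, float]
    t_statistic: float
    p_t: float
    w_statistic: float
    p_wilcoxon: float
    n: int


def cv_percent(values) -> float:
    """Coefficient of variation, 100 * sample SD / mean."""
    values = np.asarray(values, dtype=np.float64)
    mean = values.mean()
    if mean == 0:
        return math.nan
    return float(100.0 * values.std(ddof=1) / mean)


def wilcoxon_signed_rank(differences, zero_method: str = "wilcox",
                         exact_max_n: int = EXACT_WILCOXON_MAX_N
                         ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns ``(W_plus, p)`` where ``W_plus`` is the sum of ranks of the
    positive differences. All differences zero -> ``(0, nan)``.
    """
    d = np.asarray(differences, dtype=np.float64)
    if zero_method not in ("wilcox", "pratt"):
        raise DataError(f"unknown zero_method {zero_method!r}")
    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            return 0.0, math.nan
        ranks = sps.rankdata(np.abs(d))
    else:  # pratt: zeros participate in ranking, then drop
        if np.all(d == 0):
            return 0.0, math.nan
        ranks = sps.rankdata(np.abs(d))
        keep = d != 0
        d, ranks = d[keep], ranks[keep]
    w_plus = float(ranks[d > 0].sum())
    m = d.size

    if m <= exact_max_n:
        p = _exact_signflip_p(ranks, w_plus)
    else:
        mean_w = ranks.sum() / 2.0
        var_w = float((ranks ** 2).sum()) / 4.0
        z = (w_plus - mean_w) / math.sqrt(var_w)
        p = 2.0 * sps.norm.sf(abs(z))
    return w_plus, min(1.0, p)


def _exact_signflip_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^m sign assignments, by DP.

    Doubling the (mid)ranks makes them integers, so the distribution of
    2*W+ is a convolution of {0, 2*r_i} indicators — polynomial time even
    with ties.
    """
    r2 = np.round(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:counts.size - r].copy()
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_compare(values_a, values_b, zero_method: str = "wilcox") -> PairedCohortResult:
    """Compare two paired measurement series subject-by-subject.

    ``mean_difference`` is ``mean(a - b)``; the 95% CI and the t-test use
    the t distribution with n - 1 degrees of freedom on the differences.
    When every difference is zero both p-values are NaN (not applicable).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired comparison needs two equal-length 1-D series")
    n = a.size
    if n < 3:
        raise DataError("paired comparison needs n >= 3 subjects")

    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    se = sd_diff / math.sqrt(n)
    tcrit = float(sps.t.ppf(0.975, n - 1))

    if sd_diff == 0:
        t_stat = math.nan
        p_t = math.nan
        ci = (mean_diff, mean_diff)
    else:
        t_stat = mean_diff / se
        p_t = float(2.0 * sps.t.sf(abs(t_stat), n - 1))
        ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)

    w_stat, p_w = wilcoxon_signed_rank(d, zero_method=zero_method)

    return PairedCohortResult(
        summary_a=MethodSummary.from_values(a),
        summary_b=MethodSummary.from_values(b),
        mean_difference=mean_diff, se=se, ci95=ci,
        t_statistic=t_stat, p_t=p_t,
        w_statistic=w_stat, p_wilcoxon=p_w, n=n,
    )
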