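"""Between-group inference: Mann-Whitney U, distribution-free median CIs,
Cohen's d, exact two-tailed binomial test, and 2x2 chi-square.

All tests are two-tailed.  Group summaries report the median with a 95%
confidence interval: the default is the distribution-free order-statistic
(binomial-count) interval, with a seeded bootstrap-percentile alternative;
the CI method is always recorded in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import ValidationError

logger = logging.getLogger("pbspike")


@dataclass
class GroupSummary:
    n: int
    median: float
    ci_low: float
    ci_high: float
    ci_method: str


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    effect_size: float = float("nan")  # Cohen's d where applicable
    group_summaries: list = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value outside [0, 1]")


def _summaries(groups, level=0.95) -> list:
    return [
        GroupSummary(len(g), *median_ci(g, level=level), ci_method="order_statistic")
        for g in groups
    ]


def mann_whitney_u(group_a, group_b, ci_level: float = 0.95) -> GroupComparison:
    """Two-tailed Mann-Whitney U rank-sum test.

    Reports ``U = min(U_a, U_b)`` (so U = 0 signals complete separation).
    The p-value is exact when the combined sample size is at most 20 and
    there are no ties, otherwise a tie-corrected normal approximation with
    continuity correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([a, b]))  # midranks for ties
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2)
    u_b = float(a.size * b.size - u_a)
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    d = float("nan")
    if a.size >= 2 and b.size >= 2:
        try:
            d = cohens_d(a, b)
        except ValidationError:
            pass
    return GroupComparison(
        test_name=f"mann_whitney_u[{method}]",
        statistic=min(u_a, u_b),
        p_value=float(min(res.pvalue, 1.0)),
        effect_size=d,
        group_summaries=_summaries([a, b], level=ci_level),
    )


def median_ci(
    values,
    level: float = 0.95,
    method: str = "order_statistic",
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple:
    """Sample median and confidence interval.

    ``order_statistic``: the distribution-free interval ``(x_(l),
    x_(n+1-l))`` with ``l`` the largest integer whose lower binomial tail
    stays within ``(1 - level) / 2`` — coverage is conservative.  For
    n < 6 no 95% order-statistic interval exists; the full data range is
    returned with a coverage warning.  ``bootstrap``: seeded percentile
    bootstrap of the median.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValidationError("median of an empty sample")
    med = float(np.median(x))
    alpha = 1.0 - level
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        meds = np.median(
            x[rng.integers(0, n, size=(n_boot, n))], axis=1
        )
        return med, float(np.quantile(meds, alpha / 2)), float(
            np.quantile(meds, 1 - alpha / 2)
        )
    if method != "order_statistic":
        raise ValidationError(f"unknown CI method {method!r}")
    # largest l (1-indexed) with P(Bin(n, 1/2) <= l - 1) <= alpha / 2
    l = int(sps.binom.ppf(alpha / 2, n, 0.5))
    if sps.binom.cdf(l, n, 0.5) <= alpha / 2:
        l += 1
    if l < 1 or n < 6:
        logger.warning(
            "order-statistic CI undefined at %.0f%% for n=%d; "
            "returning the data range",
            100 * level,
            n,
        )
        return med, float(x[0]), float(x[-1])
    return med, float(x[l - 1]), float(x[n - l])


def cohens_d(group_a, group_b) -> float:
    """Absolute standardized mean difference with (n-1)-weighted pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Cohen's d needs n >= 2 per group")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var <= 0:
        raise ValidationError("zero pooled SD")
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled_var))


def binomial_two_tailed(
    successes: int, n: int, p0: float, method: str = "minlike"
) -> float:
    """Exact two-tailed binomial p-value.

    ``minlike`` (default) sums the probabilities of all outcomes no more
    likely than the observed one; ``double`` doubles the smaller one-sided
    tail.  Both are capped at 1.
    """
    if not 0 <= successes <= n or n < 1:
        raise ValidationError("invalid counts")
    if not 0 < p0 < 1:
        raise ValidationError("p0 must be in (0, 1)")
    if method == "minlike":
        return float(sps.binomtest(successes, n, p0).pvalue)
    if method == "double":
        lower = sps.binom.cdf(successes, n, p0)
        upper = sps.binom.sf(successes - 1, n, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValidationError(f"unknown method {method!r}")


def chi_square_2x2(table, yates: bool = True) -> GroupComparison:
    """Pearson chi-square on a 2x2 table, optional Yates correction.

    Warns when any expected cell count is below 5 (the usual validity
    caveat for the asymptotic test).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValidationError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) <= 0) or np.any(t.sum(axis=1) <= 0):
        raise ValidationError("zero margin in 2x2 table")
    stat, p, dof, expected = sps.chi2_contingency(t, correction=yates)
    if np.any(expected < 5):
        logger.warning("expected cell count below 5; chi-square approximate")
    return GroupComparison(
        test_name=f"chi_square_2x2[yates={yates}]",
        statistic=float(stat),
        p_value=float(p),
    )
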