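"""Statistical primitives shared by every analysis stage.

The pipeline needs exactly four tests and one correction: a 1-df Pearson
goodness-of-fit test against a 50/50 split (allele-retention direction),
a Pearson chi-squared test on 2x2 tables (category and locus-class
comparisons), an exact two-sided binomial test (regional mutation load),
Welch's unequal-variance t-test (per-feature methylation/expression
contrasts), and the Bonferroni threshold.  All chi-squared tests are
uncorrected: the published allele-retention p-values (e.g. 0.0025 for a
22 vs 6 split) reproduce only without the Yates continuity correction.

The two-sided binomial p-value follows the "minlike" convention (sum of
the probabilities of all outcomes no more likely than the observed one),
the same convention as R's ``binom.test``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "DegenerateInputError",
    "chisq_gof_2",
    "chisq_2x2",
    "binom_two_sided",
    "welch_t",
    "bonferroni_threshold",
]


class DegenerateInputError(ValueError):
    """Raised when a test is requested on data that cannot support it."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``df`` is float because Welch's t has fractional degrees of freedom;
    chi-squared methods always carry an integer-valued df >= 1.
    """

    statistic: float
    p_value: float
    df: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def _as_count(x, name: str) -> int:
    xi = int(x)
    if xi != x or xi < 0:
        raise ValueError(f"{name} must be a non-negative integer, got {x!r}")
    return xi


def chisq_gof_2(count_a, count_b) -> TestResult:
    """1-df Pearson goodness-of-fit of two counts against equal expectation.

    Used to ask whether allele loss is directional: under the null the
    two homozygous-in-tumour classes each expect (a+b)/2.  No continuity
    correction.  Symmetric in its arguments.
    """
    a = _as_count(count_a, "count_a")
    b = _as_count(count_b, "count_b")
    if a + b == 0:
        raise DegenerateInputError("both counts are zero")
    stat, p = _sps.chisquare([a, b])
    return TestResult(float(stat), float(min(p, 1.0)), 1, "chisq_gof_2")


def chisq_2x2(a, b, c, d) -> TestResult:
    """Pearson chi-squared on the 2x2 table [[a, b], [c, d]], uncorrected.

    Raises :class:`DegenerateInputError` when any row or column margin is
    zero (the statistic is undefined there).
    """
    table = np.array(
        [[_as_count(a, "a"), _as_count(b, "b")], [_as_count(c, "c"), _as_count(d, "d")]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("2x2 table has a zero margin")
    stat, p, df, _ = _sps.chi2_contingency(table, correction=False)
    return TestResult(float(stat), float(min(p, 1.0)), int(df), "chisq_2x2")


def binom_two_sided(k, n, p0) -> float:
    """Exact two-sided binomial p-value (minlike convention).

    Sum of P(X = i) over all i whose point probability does not exceed
    that of the observed count ``k`` under Binomial(``n``, ``p0``).
    """
    k = _as_count(k, "k")
    n = _as_count(n, "n")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"need 0 < p0 < 1, got {p0}")
    return float(_sps.binomtest(k, n, p0).pvalue)


def welch_t(values_a, values_b) -> TestResult:
    """Two-sided Welch (unequal-variance) two-sample t-test.

    Each group needs at least two values and nonzero variance; anything
    less raises :class:`DegenerateInputError` so callers can skip and
    count the feature rather than propagate NaNs.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs >= 2 values")
    if a.std() == 0.0 or b.std() == 0.0:
        raise DegenerateInputError("a group has zero variance")
    res = _sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), float(res.df), "welch_t")


def bonferroni_threshold(n_tests, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    n = int(n_tests)
    if n < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / n
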