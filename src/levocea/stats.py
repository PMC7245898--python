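"""Comparative statistics for two-arm cohorts.

Pearson's chi-square (optionally Yates-corrected) and Fisher's exact test
compare binary outcomes between arms; the Mantel-Haenszel chi-square tests
the association across LVEF strata; Student's t and Mann-Whitney U compare
continuous summaries. Exact machinery (hypergeometric tails, t, U) is
delegated to scipy; the Mantel-Haenszel statistic is computed here from the
conditional hypergeometric moments per stratum,

    E[a_i]   = r1_i c1_i / n_i
    Var[a_i] = r1_i r2_i c1_i c2_i / (n_i^2 (n_i - 1)),

with the summary statistic (|sum a_i - sum E| - 1/2 [if corrected])^2 / sum Var
referred to chi-square on 1 df. The continuity correction defaults ON, which
is the convention that reproduces the stratified p printed at 2 dp in the
source cohort (without it the p is about 0.005).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort import FourfoldTable, StratumSet
from .exceptions import DegenerateTableError, InsufficientDataError, ValidationError


class Method(str, Enum):
    PEARSON_CHI2 = "pearson_chi2"
    FISHER_EXACT = "fisher_exact"
    MANTEL_HAENSZEL = "mantel_haenszel"
    T_TEST = "t_test"
    MANN_WHITNEY = "mann_whitney"


class Sidedness(str, Enum):
    ONE_SIDED = "one_sided"
    TWO_SIDED = "two_sided"


@dataclass(frozen=True)
class TestResult:
    method: Method
    p_value: float
    statistic: float | None = None
    sidedness: Sidedness = Sidedness.TWO_SIDED
    continuity_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value outside [0,1]: {self.p_value}")


def pearson_chi2(t: FourfoldTable, correction: bool = False) -> TestResult:
    """Pearson chi-square for a fourfold table (1 df, two-sided).

    ``correction=True`` applies the Yates continuity adjustment
    (|ad-bc| - N/2, floored at zero) to the numerator.
    """
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError(f"zero marginal in table {t.counts}")
    a, b, c, d = t.counts
    n = t.n
    dev = abs(a * d - b * c)
    if correction:
        dev = max(dev - n / 2.0, 0.0)
    stat = n * dev**2 / (r1 * r2 * c1 * c2)
    return TestResult(
        method=Method.PEARSON_CHI2,
        statistic=stat,
        p_value=float(sps.chi2.sf(stat, df=1)),
        continuity_correction=correction,
    )


def fisher_exact(t: FourfoldTable, sidedness: Sidedness = Sidedness.TWO_SIDED) -> TestResult:
    """Fisher's exact test on a fourfold table.

    One-sided: hypergeometric tail probability of tables at least as extreme
    in the observed direction (toward smaller ``a`` when the intervention
    rate is the lower one). Two-sided: sum of point probabilities no larger
    than the observed table's.
    """
    sidedness = Sidedness(sidedness)
    a, b, c, d = t.counts
    if sidedness is Sidedness.ONE_SIDED:
        # direction of the observed association: a*d - b*c < 0 means the
        # intervention arm has the lower event odds, so the tail runs down.
        alternative = "less" if a * d - b * c <= 0 else "greater"
    else:
        alternative = "two-sided"
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return TestResult(method=Method.FISHER_EXACT, p_value=float(p), sidedness=sidedness)


def mantel_haenszel(s: StratumSet, continuity_correction: bool = True) -> TestResult:
    """Mantel-Haenszel chi-square across strata (1 df).

    Continuity correction defaults ON (see module docstring).
    """
    total_a = expected = variance = 0.0
    for label, t in s.strata:
        n = t.n
        if n == 0:
            raise DegenerateTableError(f"stratum {label!r} is empty")
        r1, r2, c1, c2 = t.margins()
        if n < 2:
            raise DegenerateTableError(f"stratum {label!r} has a single subject")
        total_a += t.a
        expected += r1 * c1 / n
        variance += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    if variance == 0.0:
        raise DegenerateTableError("all strata are degenerate (zero variance)")
    dev = abs(total_a - expected)
    if continuity_correction:
        dev = max(dev - 0.5, 0.0)
    stat = dev**2 / variance
    return TestResult(
        method=Method.MANTEL_HAENSZEL,
        statistic=stat,
        p_value=float(sps.chi2.sf(stat, df=1)),
        continuity_correction=continuity_correction,
    )


def continuous_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: Method | str = Method.MANN_WHITNEY,
) -> TestResult:
    """Two-sided comparison of two continuous samples.

    ``t_test`` is Student's t (equal variances, as classically reported);
    ``mann_whitney`` uses midranks, exact below n = 20 per group and the
    normal approximation with continuity correction above.
    """
    method = Method(method)
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if method is Method.T_TEST:
        if x.size < 2 or y.size < 2:
            raise InsufficientDataError("t-test needs at least 2 values per group")
        stat, p = sps.ttest_ind(x, y)
        return TestResult(method=method, statistic=float(stat), p_value=float(p))
    if method is Method.MANN_WHITNEY:
        if np.unique(np.concatenate([x, y])).size == 1:
            # all observations tied: no evidence either way
            return TestResult(method=method, statistic=float(x.size * y.size / 2), p_value=1.0)
        mode = "exact" if max(x.size, y.size) <= 20 else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=mode)
        return TestResult(method=method, statistic=float(res.statistic), p_value=float(res.pvalue))
    raise ValidationError(f"unsupported method for continuous comparison: {method}")
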