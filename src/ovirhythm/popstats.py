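"""Population comparison statistics.

Two quantities accompany the rhythmicity reports: the 'N-1' chi-squared
test for comparing two proportions of rhythmic flies (the Pearson 2x2
statistic scaled by (N-1)/N, recommended for small samples), and the
pooled-SD Cohen's d effect size for period comparisons. Routine t-tests,
ANOVA, Tukey and normality checks are delegated to scipy/statsmodels by
callers and are not re-derived here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import RecordError

__all__ = ["ProportionTest", "n1_chisq", "cohens_d"]


@dataclass(frozen=True)
class ProportionTest:
    k1: int
    n1: int
    k2: int
    n2: int
    statistic: float
    p_value: float


def n1_chisq(k1: int, n1: int, k2: int, n2: int) -> ProportionTest:
    """'N-1' chi-squared test for two independent proportions k1/n1 vs k2/n2.

    statistic = ((N-1)/N) * Pearson chi-squared of the 2x2 table,
    N = n1 + n2; two-sided p from the 1-df chi-squared tail. No minimum
    expected-cell rule is applied. Degenerate margins (all successes or
    all failures) give statistic 0, p 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise RecordError(f"group size must be >= 1, got {n}")
        if not 0 <= k <= n:
            raise RecordError(f"count {k} outside [0, {n}]")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    N = n1 + n2
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return ProportionTest(k1, n1, k2, n2, 0.0, 1.0)
    pearson = N * (a * d - b * c) ** 2 / (n1 * n2 * col1 * col2)
    statistic = (N - 1) / N * pearson
    return ProportionTest(k1, n1, k2, n2, float(statistic),
                          float(stats.chi2.sf(statistic, df=1)))


def cohens_d(sample_a, sample_b) -> float:
    """Pooled-SD Cohen's d, (mean_a - mean_b) / s_pooled, n-1 denominators."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise RecordError("each sample needs >= 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise RecordError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    if pooled == 0:
        raise RecordError("zero pooled variance: effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))
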