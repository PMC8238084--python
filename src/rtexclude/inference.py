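"""Two-sample significance testing.

The study design compares two RT samples drawn from populations that share
sigma, so a Student (pooled-variance) two-sample t-test is the appropriate
test; unequal sample sizes after outlier exclusion are handled naturally by
the pooled formula.  Tests are two-sided with alpha = 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DEFAULT_ALPHA", "TestResult", "pooled_t_statistic", "pooled_t_test"]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sample test.

    ``t`` and ``p`` are NaN (and ``significant`` False) when the test is
    undefined, i.e. when either side has fewer than two observations.
    """

    t: float
    df: int
    p: float
    significant: bool


def _t_from_stats(
    mean_a: float, var_a: float, n_a: int, mean_b: float, var_b: float, n_b: int
) -> tuple[float, int]:
    """Pooled t and degrees of freedom from per-sample summary statistics."""
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    delta = mean_a - mean_b
    if sp2 == 0.0:
        # Both samples constant: zero difference is a zero t, any other is
        # infinitely many pooled SDs away.
        t = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
    else:
        t = delta / math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return t, df


def pooled_t_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Student's pooled two-sample t statistic and its degrees of freedom.

    Both vectors must hold at least two values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    return _t_from_stats(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size
    )


def pooled_t_test(
    a: np.ndarray, b: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Two-sided Student t-test assuming equal variances.

    Parameters
    ----------
    a, b : array-like
        RT vectors of the two conditions.
    alpha : float
        Significance level; ``significant`` is ``p < alpha``.

    Returns
    -------
    TestResult
        If either side has fewer than two values the test is undefined: a
        warning is emitted and a non-significant NaN result returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        warnings.warn(
            "t-test undefined with fewer than 2 observations per side; "
            "flagging as non-significant",
            stacklevel=2,
        )
        return TestResult(t=math.nan, df=0, p=math.nan, significant=False)
    t, df = _t_from_stats(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(t=t, df=df, p=p, significant=bool(p < alpha))
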