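"""Downstream response reporting: percent-of-control and Student t.

These are the statistics used when summarising phenotype and
complementation assays: expression expressed as a percentage of an
untreated or wild-type control, and the equal-variance two-sample Student
t test (Welch's form available as an option) between two groups of
per-line means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison summary."""

    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    n_a: int
    n_b: int
    alpha: float
    significant: bool


def percent_of_control(value: float, control: float) -> float:
    """``100 * value / control``; scale-invariant in (value, control)."""
    if not np.isfinite(control) or control <= 0:
        raise DomainError(f"control must be positive, got {control}")
    if not np.isfinite(value) or value < 0:
        raise DomainError(f"value must be nonnegative, got {value}")
    return 100.0 * value / control


def student_t(group_a, group_b, alpha: float = 0.05, welch: bool = False) -> GroupComparison:
    """Two-sided two-sample t test (pooled variance by default).

    ``t`` is signed as mean_a - mean_b; df = n_a + n_b - 2 for the pooled
    form.  Degenerate data (zero pooled variance) raise rather than return
    an infinite statistic.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DomainError("group values must be finite")
    if a.size < 2 or b.size < 1 or a.size + b.size < 3:
        raise InsufficientDataError(
            f"student_t needs n_a >= 2, n_b >= 1, n_a + n_b >= 3; got {a.size}, {b.size}")
    if not (0 < alpha < 1):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1) if b.size > 1 else 0.0
    pooled = ((a.size - 1) * var_a + (b.size - 1) * var_b) / (a.size + b.size - 2)
    if pooled == 0:
        raise DomainError("zero pooled variance: degenerate groups")
    if welch:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    else:
        df = float(a.size + b.size - 2)
        se = np.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
        t = float((a.mean() - b.mean()) / se)
        p = float(2.0 * stats.t.sf(abs(t), df))
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()), t=t,
        df=df, p=p, n_a=int(a.size), n_b=int(b.size), alpha=float(alpha),
        significant=bool(p < alpha),
    )
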