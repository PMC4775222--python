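"""Statistical tests and summary conventions used for reporting.

Sample means are compared with the classical two-sample Student's t-test
(pooled variance, two-sided; Welch's variant behind a flag), correlation
coefficients are tested by transformation to a t-statistic with n−2
degrees of freedom, and distributions are contrasted with the two-sample
Kolmogorov–Smirnov test.  Dispersion is summarised as the standard error
of the mean, s.e.m. = sd/√n with the n−1 sd.  No multiple-testing
correction is applied; outputs record this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["SummaryResult", "t_test", "corr_significance", "ks_test", "summarize"]

MULTIPLE_TESTING = "none"


@dataclass
class SummaryResult:
    label: str
    n: int
    mean: float
    sem: float | None
    flag: str = ""


def t_test(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test; returns (t, p).

    Pooled-variance by default; set ``welch=True`` for unequal variances.
    Two constant samples with equal means have no evidence of a
    difference: (t, p) = (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def corr_significance(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation r at sample size n.

    Transforms r into t = r·√((n−2)/(1−r²)) and refers it to the t
    distribution with n−2 degrees of freedom.  |r| = 1 is returned as the
    p → 0 limit.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def ks_test(a: np.ndarray, b: np.ndarray, method: str = "asymp") -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test; returns (D, p).

    ``method="asymp"`` (default) uses the asymptotic Kolmogorov
    distribution with the standard effective-n correction, matching the
    convention of the original analysis; ``method="exact"`` is available
    for small samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("samples must be non-empty")
    res = sps.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def summarize(values: np.ndarray, label: str = "") -> SummaryResult:
    """Mean ± s.e.m. summary; s.e.m. is undefined (None, flagged) at n = 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    n = int(values.size)
    mean = float(np.mean(values))
    if n == 1:
        return SummaryResult(label=label, n=1, mean=mean, sem=None, flag="sem undefined at n=1")
    sem = float(np.std(values, ddof=1) / np.sqrt(n))
    return SummaryResult(label=label, n=n, mean=mean, sem=sem)
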