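"""Group-level inference shared by all analyses.

Per-subject coupling statistics (standardized MI, correlation coefficients,
quadratic beta weights) are tested against zero with a two-tailed one-sample
t-test, and multiple comparisons across the cells of one figure-level map
are controlled with the Benjamini-Hochberg step-up procedure at q = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupTestResult", "group_ttest", "bh_fdr"]


@dataclass
class GroupTestResult:
    t: float
    p: float
    df: int
    mean: float


def group_ttest(values) -> GroupTestResult:
    """Two-tailed one-sample t-test of per-subject values against zero."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ValueError("need at least 3 finite values")
    if np.ptp(v) == 0:
        raise ValueError("zero variance; t-test undefined")
    res = sps.ttest_1samp(v, 0.0)
    return GroupTestResult(t=float(res.statistic), p=float(res.pvalue),
                           df=len(v) - 1, mean=float(v.mean()))


def bh_fdr(p_values, q: float = 0.1):
    """Benjamini-Hochberg step-up FDR control.

    Sorts the p-values ascending, finds the largest k with
    p(k) <= k*q/m, and rejects every test with p <= p(k).  NaN p-values are
    excluded from the family and never rejected.

    Returns (fdr_alpha, reject): the adjusted threshold (0.0 when nothing is
    rejected) and a boolean mask aligned with the input.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    finite = np.isfinite(p)
    pv = p[finite]
    if pv.size == 0:
        return 0.0, np.zeros(p.shape, bool)
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.sort(pv)
    crit = (np.arange(1, m + 1) / m) * q
    below = order <= crit
    if not below.any():
        return 0.0, np.zeros(p.shape, bool)
    fdr_alpha = float(order[np.flatnonzero(below).max()])
    reject = np.zeros(p.shape, bool)
    reject[finite] = pv <= fdr_alpha
    return fdr_alpha, reject
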