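"""Binned quadratic (inverted-U) models of power as a function of pupil state.

Segments are sorted into 14 equidistant pupil bins; per-bin mean power is
z-scored across bins and fit with a degree-2 polynomial

    P = beta0 + beta1 * x + beta2 * x**2

where x is the per-bin mean pupil, z-scored across bins.  A negative beta2
indicates an inverted-U relationship (maximal power at intermediate arousal,
the Yerkes-Dodson pattern); beta2 is tested against zero across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import bh_fdr, group_ttest

__all__ = ["BinnedCurve", "QuadFit", "bin_by_pupil", "fit_quadratic", "quad_map",
           "group_quad_test"]


@dataclass
class BinnedCurve:
    bin_centers: np.ndarray   # mean pupil of members per bin (NaN if empty)
    bin_means: np.ndarray     # per-bin mean of the response (z-scored by default)
    bin_counts: np.ndarray
    degenerate: bool = False  # constant response: z-scoring undefined, fit skipped
    label: str = ""


@dataclass
class QuadFit:
    beta0: float
    beta1: float
    beta2: float
    sse: float


def bin_by_pupil(seg_values: np.ndarray, seg_pupil: np.ndarray, n_bins: int = 14,
                 max_empty: int = 4, zscore: bool = True, label: str = "") -> BinnedCurve:
    """Average ``seg_values`` within equidistant pupil bins.

    Bin edges are equidistant over [min, max] of ``seg_pupil``.  Empty bins
    yield NaN and are excluded from any subsequent fit; more than
    ``max_empty`` empty bins is an error.  With ``zscore=True`` the bin means
    are standardized across bins (the normalization applied before the
    quadratic fit).
    """
    v = np.asarray(seg_values, float)
    x = np.asarray(seg_pupil, float)
    if v.shape != x.shape:
        raise ValueError("seg_values and seg_pupil must align")
    ok = np.isfinite(v) & np.isfinite(x)
    v, x = v[ok], x[ok]
    if len(v) < n_bins:
        raise ValueError(f"need at least {n_bins} segments")
    if np.ptp(x) == 0:
        raise ValueError("pupil values are constant; binning undefined")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    centers = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = v[sel].mean()
            centers[b] = x[sel].mean()
    n_empty = int((counts == 0).sum())
    if n_empty > max_empty:
        raise ValueError(f"{n_empty} empty pupil bins (> {max_empty})")
    valid = counts > 0
    degenerate = bool(np.ptp(means[valid]) == 0)
    if zscore and not degenerate:
        mu = means[valid].mean()
        sd = means[valid].std()
        means = (means - mu) / sd
    return BinnedCurve(centers, means, counts, degenerate=degenerate, label=label)


def fit_quadratic(curve: BinnedCurve, min_valid_bins: int = 10) -> QuadFit:
    """Least-squares degree-2 polynomial of bin means on z-scored bin centers."""
    if curve.degenerate:
        raise ValueError("degenerate curve (constant response); fit skipped")
    ok = np.isfinite(curve.bin_means) & np.isfinite(curve.bin_centers)
    if ok.sum() < min_valid_bins:
        raise ValueError(f"only {int(ok.sum())} valid bins (< {min_valid_bins})")
    x = curve.bin_centers[ok]
    y = curve.bin_means[ok]
    if len(np.unique(x)) <= 3:
        raise ValueError("rank-deficient design: fewer than 4 distinct pupil bins")
    x = (x - x.mean()) / x.std()
    A = np.column_stack([np.ones_like(x), x, x ** 2])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    sse = float(np.sum((y - A @ coef) ** 2))
    return QuadFit(float(coef[0]), float(coef[1]), float(coef[2]), sse)


def quad_map(seg_values: np.ndarray, seg_pupil: np.ndarray, n_bins: int = 14,
             min_valid_bins: int = 10) -> np.ndarray:
    """beta2 per cell for one subject.

    ``seg_values`` has shape (n_segments, n_cells) — cells are any
    channel x frequency flattening; works identically for band power or for
    spectral-exponent series.  Returns beta2 per cell (NaN where the fit was
    skipped as degenerate).
    """
    seg_values = np.atleast_2d(np.asarray(seg_values, float))
    n_cells = seg_values.shape[1]
    beta2 = np.full(n_cells, np.nan)
    for j in range(n_cells):
        try:
            curve = bin_by_pupil(seg_values[:, j], seg_pupil, n_bins=n_bins)
            beta2[j] = fit_quadratic(curve, min_valid_bins=min_valid_bins).beta2
        except ValueError:
            continue
    return beta2


def group_quad_test(beta2_by_subject: np.ndarray, q: float = 0.1):
    """Group test of beta2 against zero per cell, BH-FDR corrected.

    ``beta2_by_subject``: (n_subjects, n_cells).  Returns (t, p, reject,
    fdr_alpha) arrays/scalars; cells with fewer than 3 finite values get NaN.
    """
    b = np.atleast_2d(np.asarray(beta2_by_subject, float))
    n_cells = b.shape[1]
    t = np.full(n_cells, np.nan)
    p = np.full(n_cells, np.nan)
    for j in range(n_cells):
        vals = b[:, j][np.isfinite(b[:, j])]
        if len(vals) < 3 or np.ptp(vals) == 0:
            continue
        res = group_ttest(vals)
        t[j], p[j] = res.t, res.p
    fdr_alpha, reject = bh_fdr(p, q=q)
    return t, p, reject, fdr_alpha
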