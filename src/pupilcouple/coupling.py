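"""Pupil-power coupling measures.

Three complementary quantifications of the coupling between a slow arousal
signal (pupil diameter or its derivative) and band-limited power envelopes:

* Gaussian-copula mutual information (GCMI), standardized against a null of
  time-shift surrogates.  GCMI is sensitive to any monotone or non-monotone
  dependence while remaining invariant to monotone marginal transforms.
* Lagged Pearson cross-correlation (+-10 s), resolving the temporal order of
  pupil and cortical fluctuations.  Sign convention: r(tau) correlates
  power(t) with pupil(t + tau), so positive lags mean neural activity
  precedes the pupil.
* Spearman rank-correlation maps at a fixed forward shift of the pupil
  (930 ms by default), the cortical-mapping statistic.

All operations consume :class:`~pupilcouple.spectral.EnvelopeStack` objects and
pair the pupil with each envelope by averaging it over the same wavelet
windows (frequency-specific temporal resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, special, stats

from .spectral import EnvelopeStack, window_average

__all__ = [
    "copnorm",
    "gcmi",
    "mi_with_surrogates",
    "xcorr_lagged",
    "bin_and_average_xcorr",
    "shifted_rho_map",
    "XCorrResult",
    "MIResult",
]


# ---------------------------------------------------------------------------
# Gaussian-copula mutual information
# ---------------------------------------------------------------------------

def copnorm(x: np.ndarray) -> np.ndarray:
    """Copula-normalize: map each sample to the normal score of its rank."""
    x = np.asarray(x, float)
    r = stats.rankdata(x, axis=-1)
    return special.ndtri(r / (x.shape[-1] + 1))


def _mi_from_rho(rho):
    return -0.5 * np.log2(1.0 - rho ** 2)


def gcmi(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian-copula mutual information between two 1-D series, in bits.

    Both variables are rank-transformed to uniform margins, mapped through the
    inverse standard-normal CDF, and the Gaussian MI -0.5*log2(1 - rho^2) of
    the transformed pair is returned.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined copula")
    cx = copnorm(x)
    cy = copnorm(y)
    rho = np.corrcoef(cx, cy)[0, 1]
    if abs(rho) >= 1.0:
        raise ValueError("degenerate copula (|rho| = 1)")
    return float(_mi_from_rho(rho))


@dataclass
class MIResult:
    """Standardized MI per channel x frequency."""

    mi: np.ndarray          # observed MI, bits (channels x freqs)
    mi_z: np.ndarray        # z of log MI vs surrogate distribution
    n_perm: int
    n_samples: np.ndarray   # samples used per frequency
    guard_s: float


def mi_with_surrogates(
    pupil: np.ndarray,
    stack: EnvelopeStack,
    n_perm: int = 200,
    guard_s: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> MIResult:
    """GCMI between pupil and each envelope, standardized by time-shift surrogates.

    The pupil (sampled at ``stack.fs``) is averaged over each wavelet window to
    match the envelope's temporal resolution.  For every channel and frequency,
    ``n_perm`` surrogate MI values are computed from circular shifts of the
    copula-normalized pupil, with shift offsets drawn uniformly outside a
    +-``guard_s`` window around zero alignment.  The z-score compares log
    observed MI with the mean/SD of log surrogate MI.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = stack.grid
    n_ch = stack.n_channels
    mi = np.full((n_ch, grid.n_freqs), np.nan)
    mi_z = np.full((n_ch, grid.n_freqs), np.nan)
    n_samples = np.zeros(grid.n_freqs, int)
    for k in range(grid.n_freqs):
        if stack.power[k].shape[1] == 0:
            continue
        p = window_average(pupil, stack, k)
        ok = stack.valid[k]
        p = p[ok]
        env = stack.power[k][:, ok]
        n = len(p)
        step = stack.actual_step_s(k)
        guard_n = int(np.ceil(guard_s / step))
        if n <= 2 * guard_n:
            raise ValueError(
                f"recording too short for guard window at {grid.centers[k]:.2f} Hz"
            )
        sp = copnorm(p)
        sp = (sp - sp.mean()) / sp.std()
        n_samples[k] = n
        for c in range(n_ch):
            se = copnorm(env[c])
            se = (se - se.mean()) / se.std()
            rho_obs = float(sp @ se) / n
            mi_obs = _mi_from_rho(np.clip(rho_obs, -0.999999, 0.999999))
            shifts = rng.integers(guard_n, n - guard_n, size=n_perm)
            idx = (np.arange(n)[None, :] + shifts[:, None]) % n
            rho_perm = (sp[idx] @ se) / n
            mi_perm = _mi_from_rho(np.clip(rho_perm, -0.999999, 0.999999))
            log_perm = np.log(mi_perm)
            sd = log_perm.std(ddof=1)
            mi[c, k] = mi_obs
            if sd == 0:
                continue  # flagged as NaN z
            mi_z[c, k] = (np.log(mi_obs) - log_perm.mean()) / sd
    return MIResult(mi=mi, mi_z=mi_z, n_perm=n_perm, n_samples=n_samples, guard_s=guard_s)


# ---------------------------------------------------------------------------
# Lagged cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class XCorrResult:
    """Per-frequency lagged correlograms.

    ``r[k]`` has shape (channels, n_lags(k)); ``lags_s[k]`` is symmetric about
    zero with the envelope's own step.  Positive lags: power precedes pupil.
    """

    lags_s: list
    r: list
    peak_lag_s: np.ndarray   # channels x freqs, signed-extremum lag in peak window
    peak_r: np.ndarray
    max_lag_s: float
    peak_window_s: float


def _pearson_xcorr(y: np.ndarray, x: np.ndarray, max_lag: int,
                   min_overlap: int = 2) -> np.ndarray:
    """Pearson r between y[:, t] and x[t + m] for m in [-max_lag, max_lag].

    FFT cross-products plus cumulative sums for per-lag means/variances.
    y: (channels, n); x: (n,).  Returns (channels, 2*max_lag + 1).
    """
    n = len(x)
    max_lag = min(max_lag, n - min_overlap)
    m = np.arange(-max_lag, max_lag + 1)
    # cross products: conv[k] = sum_j y[j] x[n-1-k+j], so sum_t y[t] x[t+m]
    # sits at k = n-1-m
    full = signal.fftconvolve(y, x[::-1][None, :], axes=1)
    C = full[:, (n - 1) - m]
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cx2 = np.concatenate(([0.0], np.cumsum(x ** 2)))
    cy = np.cumsum(y, axis=1)
    cy2 = np.cumsum(y ** 2, axis=1)
    cy = np.concatenate((np.zeros((y.shape[0], 1)), cy), axis=1)
    cy2 = np.concatenate((np.zeros((y.shape[0], 1)), cy2), axis=1)
    r = np.empty((y.shape[0], len(m)))
    for i, mm in enumerate(m):
        if mm >= 0:
            t0, t1 = 0, n - mm          # y index range
            Sx = cx[t1 + mm] - cx[t0 + mm]
            Sx2 = cx2[t1 + mm] - cx2[t0 + mm]
        else:
            t0, t1 = -mm, n
            Sx = cx[t1 + mm] - cx[t0 + mm]
            Sx2 = cx2[t1 + mm] - cx2[t0 + mm]
        L = t1 - t0
        Sy = cy[:, t1] - cy[:, t0]
        Sy2 = cy2[:, t1] - cy2[:, t0]
        num = C[:, i] - Sx * Sy / L
        den = np.sqrt(np.maximum(Sx2 - Sx ** 2 / L, 0) * np.maximum(Sy2 - Sy ** 2 / L, 0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r[:, i] = num / den
    return r


def _spearman_at_lags(y: np.ndarray, x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Spearman r of y[:, t] with x[t + m], ranking the overlapping segments."""
    n = len(x)
    out = np.empty((y.shape[0], len(lags)))
    for i, mm in enumerate(lags):
        if mm >= 0:
            ys, xs = y[:, : n - mm], x[mm:]
        else:
            ys, xs = y[:, -mm:], x[: n + mm]
        rx = stats.rankdata(xs)
        ry = stats.rankdata(ys, axis=1)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean(axis=1, keepdims=True)) / ry.std(axis=1, keepdims=True)
        out[:, i] = ry @ rx / len(xs)
    return out


def refine_peak_lag(lags: np.ndarray, r: np.ndarray, i: int) -> float:
    """Sub-sample extremum location by parabolic interpolation.

    Fits a parabola through the three correlogram points around the grid
    extremum ``i`` and returns the vertex lag; at the grid edges (or for a
    degenerate parabola) the grid lag itself is returned.  This removes the
    quantization of peak lags to the envelope's sample grid.
    """
    if i <= 0 or i >= len(lags) - 1:
        return float(lags[i])
    y0, y1, y2 = r[i - 1], r[i], r[i + 1]
    if not (np.isfinite(y0) and np.isfinite(y1) and np.isfinite(y2)):
        return float(lags[i])
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(lags[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = lags[i + 1] - lags[i]
    return float(lags[i] + delta * step)


def xcorr_lagged(
    pupil: np.ndarray,
    stack: EnvelopeStack,
    max_lag_s: float = 10.0,
    peak_window_s: float = 5.0,
    min_overlap_s: float = 30.0,
    method: str = "pearson",
    lags_s: np.ndarray | None = None,
) -> XCorrResult:
    """Lagged correlation of each power envelope with the pupil trace.

    r(tau) = corr(power(t), pupil(t + tau)); tau > 0 means cortical power
    precedes the pupil.  The peak lag is the signed extremum of r within
    +-``peak_window_s``.  ``method='spearman'`` ranks the overlapping
    segments per lag (slower; restrict with ``lags_s``).
    """
    grid = stack.grid
    n_ch = stack.n_channels
    lags_out, r_out = [], []
    peak_lag = np.full((n_ch, grid.n_freqs), np.nan)
    peak_r = np.full((n_ch, grid.n_freqs), np.nan)
    for k in range(grid.n_freqs):
        if stack.power[k].shape[1] == 0:
            lags_out.append(np.empty(0))
            r_out.append(np.empty((n_ch, 0)))
            continue
        p = window_average(pupil, stack, k)
        env = stack.power[k]
        step = stack.actual_step_s(k)
        n = len(p)
        max_lag = min(int(round(max_lag_s / step)), n - 2)
        if lags_s is not None:
            m = np.unique(np.round(np.asarray(lags_s) / step).astype(int))
        else:
            m = np.arange(-max_lag, max_lag + 1)
        if method == "pearson":
            if lags_s is not None:
                r_full = _pearson_xcorr(env, p, max_lag)
                sel = m + max_lag
                r = r_full[:, sel]
            else:
                r = _pearson_xcorr(env, p, max_lag)
        elif method == "spearman":
            r = _spearman_at_lags(env, p, m)
        else:
            raise ValueError(f"unknown method {method!r}")
        overlap = (n - np.abs(m)) * step
        r[:, overlap < min_overlap_s] = np.nan
        lags = m * step
        lags_out.append(lags)
        r_out.append(r)
        in_win = np.abs(lags) <= peak_window_s + 1e-12
        if in_win.any():
            rw = r[:, in_win]
            sub = np.where(np.isnan(rw), -np.inf, np.abs(rw))
            best = np.argmax(sub, axis=1)
            lw = lags[in_win]
            for c in range(n_ch):
                sgn = np.sign(rw[c, best[c]]) or 1.0
                peak_lag[c, k] = refine_peak_lag(lw, sgn * rw[c], int(best[c]))
            peak_r[:, k] = rw[np.arange(n_ch), best]
    return XCorrResult(
        lags_s=lags_out, r=r_out, peak_lag_s=peak_lag, peak_r=peak_r,
        max_lag_s=max_lag_s, peak_window_s=peak_window_s,
    )


def bin_and_average_xcorr(
    xc: XCorrResult,
    stack: EnvelopeStack,
    channel_coords: np.ndarray,
    bands: dict[str, tuple[float, float]] | None = None,
    n_bins: int = 39,
) -> dict[str, dict]:
    """Average correlograms within anterior-posterior channel bins and bands.

    Channels are sorted by their anterior-posterior coordinate (largest =
    most anterior first) and split into ``n_bins`` equal-count bins; any
    remainder channels are assigned to the most posterior bins.  Within each
    band, per-frequency correlograms are linearly interpolated onto the lag
    grid of the band's highest frequency before averaging over frequencies
    and channels.

    Returns {band: {"lags_s": ..., "r": (n_bins, n_lags)}}.
    """
    if bands is None:
        bands = {"2-4": (2.0, 4.0), "8-16": (8.0, 16.0), "64-128": (64.0, 128.0)}
    coords = np.asarray(channel_coords, float)
    n_ch = len(coords)
    order = np.argsort(-coords, kind="stable")  # anterior (large coord) first
    base, rem = divmod(n_ch, n_bins)
    if base == 0:
        raise ValueError(f"need at least {n_bins} channels for {n_bins} bins")
    sizes = np.full(n_bins, base)
    if rem:
        sizes[-rem:] += 1  # extras go to the most posterior bins
    edges = np.concatenate(([0], np.cumsum(sizes)))
    out = {}
    grid = stack.grid
    for name, (lo, hi) in bands.items():
        ks = [k for k in grid.band_indices(lo, hi) if len(xc.lags_s[k])]
        if not ks:
            continue
        k_ref = ks[int(np.argmax(grid.centers[ks]))]
        lag_ref = xc.lags_s[k_ref]
        per_freq = []
        for k in ks:
            r = xc.r[k]
            if k == k_ref:
                per_freq.append(r)
            else:
                per_freq.append(
                    np.stack([np.interp(lag_ref, xc.lags_s[k], r[c]) for c in range(n_ch)])
                )
        band_r = np.nanmean(np.stack(per_freq), axis=0)  # channels x lags
        binned = np.stack([
            band_r[order[edges[b]:edges[b + 1]]].mean(axis=0) for b in range(n_bins)
        ])
        out[name] = {"lags_s": lag_ref, "r": binned}
    return out


# ---------------------------------------------------------------------------
# Shifted rank-correlation maps
# ---------------------------------------------------------------------------

def shifted_rho_map(
    pupil: np.ndarray,
    stack: EnvelopeStack,
    shift_s: float = 0.93,
) -> np.ndarray:
    """Spearman correlation of power(t) with pupil(t + shift_s), per channel x freq.

    The forward shift compensates the lag of the peripheral pupil response;
    use ``shift_s=0`` for the pupil derivative.  Returns (channels, n_freqs).
    """
    grid = stack.grid
    n_ch = stack.n_channels
    rho = np.full((n_ch, grid.n_freqs), np.nan)
    for k in range(grid.n_freqs):
        if stack.power[k].shape[1] == 0:
            continue
        p = window_average(pupil, stack, k)
        env = stack.power[k]
        step = stack.actual_step_s(k)
        m = int(round(shift_s / step))
        n = len(p)
        if abs(m) >= n - 2:
            raise ValueError("shift exceeds envelope duration")
        if m >= 0:
            ys, xs = env[:, : n - m], p[m:]
        else:
            ys, xs = env[:, -m:], p[: n + m]
        for c in range(n_ch):
            rho[c, k] = stats.spearmanr(ys[c], xs).statistic
    return rho
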