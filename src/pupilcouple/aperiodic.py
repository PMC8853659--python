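"""Parameterization of power spectra into aperiodic and periodic components.

A spectrum is modeled in log10-power space as an aperiodic component

    L(f) = offset - exponent * log10(f)

(a Lorentzian with the knee fixed at zero) plus up to ``max_n_peaks``
Gaussian peaks.  The exponent chi describes the 1/f^chi background and is
used here as a time-resolved state variable: fit per 2-s segment, it can be
correlated with simultaneous pupil-linked arousal.  The flattened residual
(log spectrum minus aperiodic curve) isolates periodic, oscillatory power.

The fitting procedure:

1. seed the aperiodic component by least squares of log power on log frequency;
2. robust refit using only points at or below the seeded curve (residuals
   below the 2.5th percentile of the positive-clipped residuals), which
   excludes oscillatory peaks;
3. iteratively extract Gaussians from the flattened spectrum, largest
   residual first, until the next candidate falls below the detection
   threshold (``max(min_peak_height, peak_threshold * std)``) or the peak
   budget is exhausted;
4. jointly refine all Gaussian parameters by bounded least squares;
5. refit the aperiodic component on the peak-subtracted spectrum.

All internal constants are fixed for determinism.  Peak "bandwidth" bounds
are interpreted as bounds on 2*sigma of the Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["AperiodicFit", "SpectralModel", "fit_spectrum",
           "exponent_series", "residual_band_power", "ExponentSeries"]


@dataclass
class AperiodicFit:
    offset: float
    exponent: float
    peaks: list = field(default_factory=list)  # (center_hz, height_log10, sigma_hz)
    fit_range: tuple = (3.0, 40.0)
    r_squared: float = np.nan
    freqs: np.ndarray | None = None
    residual: np.ndarray | None = None         # log10 psd - aperiodic curve
    converged: bool = True

    def aperiodic_curve(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)

    def peak_curve(self, freqs: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(freqs, float))
        for c, h, s in self.peaks:
            out += h * np.exp(-((freqs - c) ** 2) / (2.0 * s ** 2))
        return out


def _gaussians(f, *params):
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        c, h, s = params[i:i + 3]
        out += h * np.exp(-((f - c) ** 2) / (2.0 * s ** 2))
    return out


def _gaussians_jac(f, *params):
    cols = []
    for i in range(0, len(params), 3):
        c, h, s = params[i:i + 3]
        d = f - c
        e = np.exp(-(d ** 2) / (2.0 * s ** 2))
        cols += [h * e * d / s ** 2, e, h * e * d ** 2 / s ** 3]
    return np.column_stack(cols)


class SpectralModel:
    """Fit the aperiodic + peaks model to power spectra.

    Parameters
    ----------
    fit_range : (lo, hi) frequency range in Hz used for the fit.
    max_n_peaks : maximum number of Gaussian components.
    min_peak_height : absolute detection floor in log10-power units.
    peak_threshold : relative detection threshold in units of the standard
        deviation of the flattened spectrum.
    peak_width_limits : bounds on the full bandwidth (2*sigma) of each
        Gaussian, in Hz.
    """

    _robust_percentile = 2.5

    def __init__(self, fit_range=(3.0, 40.0), max_n_peaks=6, min_peak_height=0.05,
                 peak_threshold=2.0, peak_width_limits=(1.0, 8.0)):
        self.fit_range = tuple(fit_range)
        self.max_n_peaks = int(max_n_peaks)
        self.min_peak_height = float(min_peak_height)
        self.peak_threshold = float(peak_threshold)
        self.peak_width_limits = tuple(peak_width_limits)

    # -- internals -----------------------------------------------------

    @staticmethod
    def _lsq_aperiodic(logf, y):
        A = np.column_stack([np.ones_like(logf), -logf])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return coef  # offset, exponent

    def _robust_aperiodic(self, logf, y):
        off, exp_ = self._lsq_aperiodic(logf, y)
        resid = y - (off - exp_ * logf)
        clipped = np.where(resid < 0, 0.0, resid)
        thresh = np.percentile(clipped, self._robust_percentile)
        mask = clipped <= thresh
        if mask.sum() < 2:
            mask = np.ones_like(mask)
        return self._lsq_aperiodic(logf[mask], y[mask])

    def _guess_peaks(self, f, flat):
        sig_lo, sig_hi = self.peak_width_limits[0] / 2, self.peak_width_limits[1] / 2
        guesses = []
        work = flat.copy()
        for _ in range(self.max_n_peaks):
            i = int(np.argmax(work))
            h = work[i]
            if h < max(self.min_peak_height, self.peak_threshold * np.std(work)):
                break
            c = f[i]
            # estimate sigma from the half-height crossing nearest the peak
            half = h / 2.0
            lo = i
            while lo > 0 and work[lo] > half:
                lo -= 1
            hi = i
            while hi < len(work) - 1 and work[hi] > half:
                hi += 1
            fwhm_half = min(f[i] - f[lo], f[hi] - f[i])
            sigma = np.clip(2.0 * fwhm_half / 2.355, sig_lo, sig_hi)
            guesses.append((c, h, sigma))
            work = work - h * np.exp(-((f - c) ** 2) / (2.0 * sigma ** 2))
        return guesses

    def _refine_peaks(self, f, flat, guesses):
        if not guesses:
            return []
        sig_lo, sig_hi = self.peak_width_limits[0] / 2, self.peak_width_limits[1] / 2
        p0, lo, hi = [], [], []
        for c, h, s in guesses:
            p0 += [c, h, s]
            lo += [max(f[0], c - 2 * s), 0.0, sig_lo]
            hi += [min(f[-1], c + 2 * s), np.inf, sig_hi]
        p0 = np.clip(p0, lo, hi)
        try:
            popt, _ = optimize.curve_fit(
                _gaussians, f, flat, p0=p0, bounds=(lo, hi), maxfev=3000,
                jac=_gaussians_jac, xtol=1e-6, ftol=1e-6)
        except (RuntimeError, ValueError):
            popt = np.asarray(p0)  # keep the guesses if refinement fails
        peaks = [tuple(popt[i:i + 3]) for i in range(0, len(popt), 3)]
        return [p for p in peaks if p[1] >= self.min_peak_height]

    # -- public API ----------------------------------------------------

    def fit(self, freqs: np.ndarray, psd: np.ndarray) -> AperiodicFit:
        freqs = np.asarray(freqs, float)
        psd = np.asarray(psd, float)
        sel = (freqs >= self.fit_range[0]) & (freqs <= self.fit_range[1])
        f = freqs[sel]
        p = psd[sel]
        if f.size < 4:
            raise ValueError("too few frequency bins in fit range")
        if not np.all(np.isfinite(p)) or np.any(p <= 0):
            raise ValueError("PSD must be finite and positive on the fit range")
        y = np.log10(p)
        logf = np.log10(f)
        try:
            off, exp_ = self._robust_aperiodic(logf, y)
            flat = y - (off - exp_ * logf)
            peaks = self._refine_peaks(f, flat, self._guess_peaks(f, flat))
            y_peaks = _gaussians(f, *np.ravel(peaks)) if peaks else 0.0
            off, exp_ = self._lsq_aperiodic(logf, y - y_peaks)
        except np.linalg.LinAlgError:
            return AperiodicFit(np.nan, np.nan, [], self.fit_range,
                                freqs=f, residual=None, converged=False)
        ap = off - exp_ * logf
        model = ap + (_gaussians(f, *np.ravel(peaks)) if peaks else 0.0)
        ss_res = np.sum((y - model) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return AperiodicFit(
            offset=float(off), exponent=float(exp_),
            peaks=sorted(peaks, key=lambda q: -q[1]),
            fit_range=self.fit_range, r_squared=float(r2),
            freqs=f, residual=y - ap, converged=True,
        )


def fit_spectrum(psd, freq_axis, fit_range=(3.0, 40.0), max_peaks=6,
                 min_height=0.05, width_bounds=(1.0, 8.0),
                 peak_threshold=2.0) -> AperiodicFit:
    """Functional wrapper around :class:`SpectralModel`."""
    model = SpectralModel(fit_range=fit_range, max_n_peaks=max_peaks,
                          min_peak_height=min_height, peak_threshold=peak_threshold,
                          peak_width_limits=width_bounds)
    return model.fit(freq_axis, psd)


@dataclass
class ExponentSeries:
    exponents: np.ndarray
    seg_pupil: np.ndarray
    seg_pupil_deriv: np.ndarray
    fits: list
    n_failed: int
    binned_pupil: np.ndarray | None = None     # 14-bin mean-exponent-by-pupil curve
    binned_exponent: np.ndarray | None = None

    def corr_with_pupil(self, method: str = "pearson", use_deriv: bool = False):
        """Correlation of the exponent series with segment-mean pupil."""
        x = self.seg_pupil_deriv if use_deriv else self.seg_pupil
        ok = np.isfinite(self.exponents) & np.isfinite(x)
        e = self.exponents[ok]
        xv = x[ok]
        if np.ptp(e) == 0 or np.ptp(xv) == 0:
            return 0.0  # zero-variance guard: no association by convention
        if method == "pearson":
            return float(stats.pearsonr(e, xv).statistic)
        if method == "spearman":
            return float(stats.spearmanr(e, xv).statistic)
        raise ValueError(f"unknown method {method!r}")


def exponent_series(seg_spectra, channel: int = 0, model: SpectralModel | None = None,
                    max_failed_frac: float = 0.2, n_bins: int = 14) -> ExponentSeries:
    """Fit the spectral model per 2-s segment; align exponents with pupil.

    ``seg_spectra`` is a :class:`~pupilcouple.spectral.SegmentedSpectra`;
    the PSD of ``channel`` is parameterized segment by segment.
    """
    if model is None:
        model = SpectralModel()
    psd = seg_spectra.psd[:, channel, :]
    n_seg = psd.shape[0]
    if n_seg < 14:
        raise ValueError("need at least 14 segments")
    exps = np.full(n_seg, np.nan)
    fits = []
    n_failed = 0
    for i in range(n_seg):
        try:
            fit = model.fit(seg_spectra.freqs, psd[i])
            if not fit.converged or not np.isfinite(fit.exponent):
                n_failed += 1
            else:
                exps[i] = fit.exponent
            fits.append(fit)
        except ValueError:
            n_failed += 1
            fits.append(None)
    if n_failed > max_failed_frac * n_seg:
        raise ValueError(f"{n_failed}/{n_seg} segment fits failed")
    out = ExponentSeries(exps, seg_spectra.seg_pupil, seg_spectra.seg_pupil_deriv,
                         fits, n_failed)
    ok = np.isfinite(exps)
    if np.ptp(seg_spectra.seg_pupil[ok]) > 0:
        from .nonlinearity import bin_by_pupil
        try:
            curve = bin_by_pupil(exps[ok], seg_spectra.seg_pupil[ok],
                                 n_bins=n_bins, zscore=False)
            out.binned_pupil = curve.bin_centers
            out.binned_exponent = curve.bin_means
        except ValueError:
            pass  # too many empty bins; curve unavailable
    return out


def residual_band_power(seg_spectra, fits, grid=None):
    """Per-segment residual (periodic-only) power in each half-octave band.

    For every grid center within the fit range, the flattened residual
    spectrum (log10 power minus the segment's aperiodic curve) is averaged
    over the half-octave band, clipped to the fit range.  Bands lying wholly
    outside the fit range are excluded.

    Returns (centers_used, residual_power[segments, centers]).
    """
    from .spectral import make_grid
    if grid is None:
        grid = make_grid()
    valid_fits = [f for f in fits if f is not None and f.converged]
    if not valid_fits:
        raise ValueError("no valid fits")
    lo_r, hi_r = valid_fits[0].fit_range
    centers, cols = [], []
    for k in range(grid.n_freqs):
        c = grid.centers[k]
        if c < lo_r or c > hi_r:
            continue
        b_lo = max(grid.band_lo[k], lo_r)
        b_hi = min(grid.band_hi[k], hi_r)
        vals = np.full(len(fits), np.nan)
        for i, fit in enumerate(fits):
            if fit is None or not fit.converged:
                continue
            sel = (fit.freqs >= b_lo) & (fit.freqs <= b_hi)
            if not sel.any():
                continue
            vals[i] = fit.residual[sel].mean()
        if np.all(np.isnan(vals)):
            warnings.warn(f"band at {c:.2f} Hz outside fit support; excluded")
            continue
        centers.append(c)
        cols.append(vals)
    return np.asarray(centers), np.stack(cols, axis=1)
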