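"""Pupil preprocessing: blink handling, event-response removal, filtering.

The processing chain mirrors standard pupillometry practice:

1. pupil area is converted to diameter (d = 2*sqrt(a/pi)) to linearize the
   size measure;
2. blink gaps (NaN or sentinel runs) are padded by a safety margin and
   linearly interpolated; a second velocity-based pass removes residual
   spikes and jumps;
3. canonical pupil responses to blinks and saccades — a gamma-family
   impulse response peaking 930 ms after the event — are estimated by
   least squares and subtracted;
4. the trace is band-pass filtered to 0.005-2 Hz (second-order Butterworth,
   forward-reverse two-pass, hence zero phase), resampled to the 400 Hz
   analysis rate, and differentiated (first-order forward difference).

The result is a :class:`PupilTrace` carrying the diameter, its derivative,
and a mask of every interpolated sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .aperiodic import AperiodicFit, SpectralModel

__all__ = [
    "PupilTrace", "PupilSpectrum", "area_to_diameter", "detect_and_interpolate_blinks",
    "canonical_kernel", "remove_event_responses", "bandpass_zero_phase",
    "bandpass_downsample",
    "preprocess_pupil", "pupil_spectrum",
]

ANALYSIS_FS = 400.0


@dataclass
class PupilTrace:
    t: np.ndarray
    diameter: np.ndarray
    derivative: np.ndarray
    fs: float
    interp_mask: np.ndarray
    provenance: list = field(default_factory=list)

    @property
    def interp_fraction(self) -> float:
        return float(self.interp_mask.mean())


def area_to_diameter(area_series: np.ndarray) -> np.ndarray:
    """Convert pupil area to diameter: d = 2*sqrt(a/pi). NaN is preserved."""
    a = np.asarray(area_series, float)
    finite = np.isfinite(a)
    if np.any(a[finite] < 0):
        raise ValueError("negative pupil area")
    out = np.full_like(a, np.nan)
    out[finite] = 2.0 * np.sqrt(a[finite] / np.pi)
    return out


def _runs(mask: np.ndarray):
    """Start/stop (exclusive) index pairs of True runs."""
    m = np.asarray(mask, bool)
    d = np.diff(m.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        stops = np.concatenate((stops, [len(m)]))
    return list(zip(starts, stops))


def detect_and_interpolate_blinks(
    raw: np.ndarray,
    fs: float,
    sentinel: float | None = None,
    pad_s: float = 0.150,
    velocity_k: float = 16.0,
    spike_pad_s: float = 0.050,
    max_interp_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate blink gaps and residual artifacts.

    Gaps (NaN or ``sentinel`` samples) are padded by ``pad_s`` on each side
    and linearly interpolated.  A second pass marks velocity outliers
    (|dx/dt| > velocity_k * MAD of the velocity) with a shorter pad and
    interpolates them too.  Returns (clean_trace, interp_mask).
    """
    x = np.asarray(raw, float).copy()
    n = len(x)
    bad = ~np.isfinite(x)
    if sentinel is not None:
        bad |= x == sentinel
    if bad.all():
        raise ValueError("trace entirely artifactual")
    mask = np.zeros(n, bool)
    pad = int(round(pad_s * fs))
    for s0, s1 in _runs(bad):
        mask[max(0, s0 - pad):min(n, s1 + pad)] = True
    x = _interp_masked(x, mask)
    # second pass: velocity outliers (spikes, jumps)
    v = np.diff(x, prepend=x[0]) * fs
    if n > 1:
        v[0] = v[1]  # prepend would otherwise fake a jump at the boundary
    mad = np.median(np.abs(v - np.median(v)))
    if mad > 0:
        spikes = np.abs(v - np.median(v)) > velocity_k * mad
        if spikes.any():
            spad = int(round(spike_pad_s * fs))
            smask = np.zeros(n, bool)
            for s0, s1 in _runs(spikes):
                smask[max(0, s0 - spad):min(n, s1 + spad)] = True
            mask |= smask
            x = _interp_masked(x, mask)
    frac = mask.mean()
    if frac > max_interp_frac:
        warnings.warn(f"{frac:.1%} of samples interpolated (> {max_interp_frac:.0%})")
    return x, mask


def _interp_masked(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = x.copy()
    good = ~mask & np.isfinite(x)
    if good.sum() < 2:
        raise ValueError("trace entirely artifactual")
    idx = np.arange(len(x))
    out[~good] = np.interp(idx[~good], idx[good], x[good])
    return out


def canonical_kernel(fs: float, w: float = 10.1, t_max: float = 0.93,
                     duration_s: float = 4.0) -> np.ndarray:
    """Gamma-family pupil impulse response h(t) = t^w * exp(-t/tau), peak at t_max.

    With tau = t_max / w the response peaks at ``t_max`` (930 ms, the average
    latency of peak dilation after an arousing event); normalized to unit peak.
    """
    tau = t_max / w
    t = np.arange(0, int(round(duration_s * fs))) / fs
    with np.errstate(divide="ignore"):
        h = t ** w * np.exp(-t / tau)
    h[~np.isfinite(h)] = 0.0
    peak = h.max()
    return h / peak if peak > 0 else h


def remove_event_responses(
    trace: np.ndarray,
    fs: float,
    blink_times: np.ndarray | None = None,
    saccade_times: np.ndarray | None = None,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Regress out canonical responses to blink/saccade events.

    Impulse trains at the event times are convolved with the canonical
    kernel; one amplitude per event type is fit by least squares and the
    fitted responses are subtracted.  With no events the input is returned
    unchanged.
    """
    x = np.asarray(trace, float)
    n = len(x)
    if kernel is None:
        kernel = canonical_kernel(fs)
    regs = []
    for times in (blink_times, saccade_times):
        if times is None or len(times) == 0:
            continue
        imp = np.zeros(n)
        idx = np.round(np.asarray(times, float) * fs).astype(int)
        if np.any((idx < 0) | (idx >= n)):
            raise ValueError("event times outside trace span")
        np.add.at(imp, idx, 1.0)
        regs.append(signal.fftconvolve(imp, kernel)[:n])
    if not regs:
        return x.copy()
    A = np.column_stack(regs + [np.ones(n)])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    fitted = A[:, :-1] @ coef[:-1]
    return x - fitted


def _band_sos(fs: float, band=(0.005, 2.0), order: int = 2):
    hp = signal.butter(order, band[0], btype="highpass", fs=fs, output="sos")
    lp = signal.butter(order, band[1], btype="lowpass", fs=fs, output="sos")
    return np.vstack([hp, lp])


def bandpass_zero_phase(x: np.ndarray, fs: float,
                        band: tuple[float, float] = (0.005, 2.0),
                        order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-reverse response).

    Applies the squared magnitude response of a second-order Butterworth
    high-pass/low-pass cascade — exactly what a forward-reverse two-pass
    recursive filter realizes — in the frequency domain, on a
    reflection-padded copy of the signal.  A 0.005 Hz corner is ~1e-5 of a
    kHz sampling rate, where time-domain biquads are numerically degenerate
    (poles indistinguishable from +1) and their transients outlast the
    recording; the spectral form is exact at any corner.
    """
    x = np.asarray(x, float)
    n = len(x)
    x = x - x.mean()
    xp = np.concatenate([x[::-1], x, x[::-1]])   # reflect to soften wraparound
    f = np.fft.rfftfreq(len(xp), 1.0 / fs)
    f2o = f ** (2 * order)
    h_hp = f2o / (f2o + band[0] ** (2 * order))
    h_lp = band[1] ** (2 * order) / (band[1] ** (2 * order) + f2o)
    H = h_hp * h_lp
    y = np.fft.irfft(np.fft.rfft(xp) * H, len(xp))
    return y[n:2 * n]


def bandpass_downsample(
    trace: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.005, 2.0),
    target_fs: float = ANALYSIS_FS,
    interp_mask: np.ndarray | None = None,
    t0: float = 0.0,
    allow_upsample: bool = False,
    provenance: list | None = None,
) -> PupilTrace:
    """Zero-phase 0.005-2 Hz band-pass, resample to 400 Hz, differentiate.

    The band-pass (second-order Butterworth sections, applied forward and
    reverse) removes DC and confines the trace to the arousal-relevant band;
    the 2 Hz low-pass also serves as the anti-alias filter for the polyphase
    resampling.  The derivative is a first-order forward difference scaled
    by the sampling rate, with the last value repeated to preserve length.
    """
    x = np.asarray(trace, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace must be gap-free before filtering")
    y = bandpass_zero_phase(x, fs, band)
    if fs == target_fs:
        z = y
        mask = np.zeros(len(y), bool) if interp_mask is None else np.asarray(interp_mask, bool)
    else:
        if fs < target_fs and not allow_upsample:
            warnings.warn(
                f"input rate {fs} Hz below analysis rate {target_fs} Hz; "
                "keeping native rate (set allow_upsample=True to upsample)")
            target_fs = fs
            z = y
        else:
            from fractions import Fraction
            frac = Fraction(target_fs / fs).limit_denominator(1000)
            z = signal.resample_poly(y, frac.numerator, frac.denominator)
        if interp_mask is None:
            mask = np.zeros(len(z), bool)
        else:
            ti = t0 + np.arange(len(z)) / target_fs
            src = np.minimum((ti * fs).astype(int), len(x) - 1)
            mask = np.asarray(interp_mask, bool)[src]
    deriv = np.empty_like(z)
    deriv[:-1] = np.diff(z) * target_fs
    deriv[-1] = deriv[-2] if len(z) > 1 else 0.0
    t = t0 + np.arange(len(z)) / target_fs
    prov = list(provenance or []) + [f"bandpass {band[0]}-{band[1]} Hz",
                                     f"resample {target_fs} Hz", "derivative"]
    return PupilTrace(t=t, diameter=z, derivative=deriv, fs=target_fs,
                      interp_mask=mask, provenance=prov)


def preprocess_pupil(
    raw: np.ndarray,
    fs: float,
    is_area: bool = False,
    sentinel: float | None = None,
    blink_times: np.ndarray | None = None,
    saccade_times: np.ndarray | None = None,
    remove_responses: bool = True,
    target_fs: float = ANALYSIS_FS,
) -> PupilTrace:
    """Full preprocessing chain from a raw pupil recording."""
    prov = []
    x = np.asarray(raw, float)
    if is_area:
        x = area_to_diameter(x)
        prov.append("area->diameter")
    x, mask = detect_and_interpolate_blinks(x, fs, sentinel=sentinel)
    prov.append("blink interpolation")
    if blink_times is None and mask.any():
        blink_times = np.array([s0 / fs for s0, _ in _runs(mask)])
    if remove_responses and (
            (blink_times is not None and len(blink_times)) or
            (saccade_times is not None and len(saccade_times))):
        x = remove_event_responses(x, fs, blink_times, saccade_times)
        prov.append("canonical response removal")
    return bandpass_downsample(x, fs, target_fs=target_fs, interp_mask=mask,
                               provenance=prov)


@dataclass
class PupilSpectrum:
    freqs: np.ndarray
    psd: np.ndarray
    fit: AperiodicFit
    hippus_freq_hz: float   # NaN when no peak detected
    exponent: float


def pupil_spectrum(
    trace: PupilTrace | np.ndarray,
    fs: float | None = None,
    smoothing_hz: float = 0.035,
    nfft: int = 2 ** 19,
    f_range: tuple[float, float] = (0.005, 2.0),
    n_grid: int = 120,
    max_peaks: int = 3,
    peak_threshold: float = 0.5,
    width_bounds: tuple[float, float] = (0.1, 0.5),
) -> PupilSpectrum:
    """Multitaper spectrum of the standardized pupil trace + Hippus parameters.

    DPSS tapers with +-``smoothing_hz`` half-bandwidth are applied to the
    z-scored trace, zero-padded to ``nfft`` samples, and the spectrum is
    evaluated on a log-spaced grid over 0.005-2 Hz.  The aperiodic+peaks
    parameterization (max 3 peaks, detection threshold 0.5 SD, peak widths
    0.1-0.5 Hz) yields the pupil spectral exponent and the Hippus peak
    frequency (the strongest detected peak).
    """
    if isinstance(trace, PupilTrace):
        x = trace.diameter
        fs = trace.fs
    else:
        x = np.asarray(trace, float)
        if fs is None:
            raise ValueError("fs required for array input")
    n = len(x)
    dur = n / fs
    if dur < 10:
        raise ValueError("trace shorter than 10 s")
    if dur < 60:
        warnings.warn("trace shorter than 60 s; spectral estimates unreliable")
    x = (x - x.mean()) / x.std()
    nw = dur * smoothing_hz
    k_tapers = max(1, int(2 * nw) - 1)
    tapers = signal.windows.dpss(n, nw, Kmax=k_tapers)
    nfft = max(nfft, int(2 ** np.ceil(np.log2(n))))
    psd_acc = None
    for tap in tapers:
        spec = np.abs(np.fft.rfft(tap * x, nfft)) ** 2
        psd_acc = spec if psd_acc is None else psd_acc + spec
    psd_full = psd_acc / k_tapers * (2.0 / fs)
    freqs_full = np.fft.rfftfreq(nfft, 1.0 / fs)
    grid = np.logspace(np.log10(f_range[0]), np.log10(f_range[1]), n_grid)
    psd = np.interp(grid, freqs_full, psd_full)
    model = SpectralModel(fit_range=f_range, max_n_peaks=max_peaks,
                          min_peak_height=0.05, peak_threshold=peak_threshold,
                          peak_width_limits=width_bounds)
    fit = model.fit(grid, psd)
    hippus = fit.peaks[0][0] if fit.peaks else np.nan
    return PupilSpectrum(freqs=grid, psd=psd, fit=fit,
                         hippus_freq_hz=float(hippus), exponent=fit.exponent)
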