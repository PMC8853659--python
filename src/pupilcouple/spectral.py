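"""Frequency-resolved spectral estimates of neural time series.

Two complementary decompositions are provided:

* Morlet-wavelet power envelopes on a log-spaced 25-frequency grid
  (2-128 Hz, half-octave bands, 80% window overlap), the canonical
  representation for band-limited amplitude dynamics.
* Non-overlapping 2-s Welch segments at 0.5 Hz resolution, paired with
  segment-mean pupil values, the representation used for spectral
  parameterization and binned pupil-power models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "FrequencyGrid",
    "EnvelopeStack",
    "SegmentedSpectra",
    "make_grid",
    "wavelet_envelopes",
    "window_average",
    "segment_spectra",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Log-spaced center frequencies with half-octave bands.

    ``sigma_t`` is the temporal width of the Morlet wavelet at each center,
    chosen so that +-1 sigma_f spans the half-octave band; ``step_s`` is the
    spacing of successive analysis windows (80% overlap of the +-3 sigma_t
    support).
    """

    centers: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    sigma_t: np.ndarray
    step_s: np.ndarray

    @property
    def n_freqs(self) -> int:
        return len(self.centers)

    def band_indices(self, lo: float, hi: float) -> np.ndarray:
        """Indices of centers falling within [lo, hi] (inclusive)."""
        return np.flatnonzero((self.centers >= lo * 0.999) & (self.centers <= hi * 1.001))


def make_grid(n_freqs: int = 25, f_min: float = 2.0) -> FrequencyGrid:
    """Build the standard grid: f_k = f_min * 2**(k/4), k = 0..n-1.

    With the defaults this spans 2-128 Hz in quarter-octave steps, each
    frequency analyzed within the half-octave band around its center.
    """
    k = np.arange(n_freqs)
    centers = f_min * 2.0 ** (k / 4.0)
    band_lo = centers * 2.0 ** (-0.25)
    band_hi = centers * 2.0 ** (0.25)
    sigma_f = (band_hi - band_lo) / 2.0
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    window_s = 6.0 * sigma_t          # +-3 sigma_t support
    step_s = 0.2 * window_s           # 80% overlap
    return FrequencyGrid(centers, band_lo, band_hi, sigma_t, step_s)


@dataclass
class EnvelopeStack:
    """Per-frequency power envelopes (channels x windows), ragged over frequency.

    ``power[k]`` holds squared wavelet magnitudes for grid frequency k, sampled
    at window centers ``times[k]`` spaced by ``grid.step_s[k]`` (rounded to the
    sample grid).  ``valid[k]`` is False for windows whose support touched
    masked samples.  ``half_n[k]``/``center_idx[k]`` record the exact window
    geometry so companion series (e.g. pupil) can be reduced identically.
    """

    grid: FrequencyGrid
    fs: float
    power: list = field(default_factory=list)
    times: list = field(default_factory=list)
    valid: list = field(default_factory=list)
    half_n: list = field(default_factory=list)
    center_idx: list = field(default_factory=list)
    t0: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.power[0].shape[0]

    def step_samples(self, k: int) -> int:
        idx = self.center_idx[k]
        return int(idx[1] - idx[0]) if len(idx) > 1 else 1

    def actual_step_s(self, k: int) -> float:
        return self.step_samples(k) / self.fs


def _morlet(f: float, sigma_t: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet truncated at +-3 sigma_t, unit energy."""
    half = int(round(3.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2)) * np.exp(-2j * np.pi * f * t)
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / fs)  # integral |w|^2 dt = 1
    return w


def wavelet_envelopes(
    data: np.ndarray,
    fs: float,
    grid: FrequencyGrid | None = None,
    mask: np.ndarray | None = None,
    t0: float = 0.0,
    freq_indices: np.ndarray | None = None,
) -> EnvelopeStack:
    """Compute Morlet power envelopes Y(t, f) = |X(t, f)|^2.

    Parameters
    ----------
    data : (n_channels, n_samples) array
    fs : sampling rate in Hz
    mask : optional boolean array, True where samples are artifactual;
        windows overlapping masked samples are flagged invalid.
    freq_indices : restrict computation to a subset of grid frequencies
        (the remaining entries hold empty arrays).
    """
    if grid is None:
        grid = make_grid()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n = data.shape
    all_masked = mask is not None and np.asarray(mask, bool).all()
    if all_masked:
        raise ValueError("all samples are masked")
    if mask is not None:
        mask = np.asarray(mask, bool)
    stack = EnvelopeStack(grid=grid, fs=fs, t0=t0)
    ks = np.arange(grid.n_freqs) if freq_indices is None else np.asarray(freq_indices)
    for k in range(grid.n_freqs):
        if k not in ks:
            stack.power.append(np.empty((n_ch, 0)))
            stack.times.append(np.empty(0))
            stack.valid.append(np.empty(0, bool))
            stack.half_n.append(0)
            stack.center_idx.append(np.empty(0, int))
            continue
        f = grid.centers[k]
        sig_t = grid.sigma_t[k]
        w = _morlet(f, sig_t, fs)
        half = (len(w) - 1) // 2
        if 2 * half + 1 > n:
            raise ValueError(
                f"recording too short for {f:.2f} Hz wavelet support "
                f"({2 * half + 1} samples needed, {n} available)"
            )
        step_n = max(1, int(round(grid.step_s[k] * fs)))
        coef = signal.oaconvolve(data, np.conj(w[::-1])[None, :], mode="valid", axes=1)
        idx = np.arange(0, coef.shape[1], step_n)
        power = np.abs(coef[:, idx]) ** 2
        centers = half + idx
        valid = np.ones(len(idx), bool)
        if mask is not None:
            bad = np.convolve(mask.astype(float), np.ones(2 * half + 1), mode="valid") > 0
            valid = ~bad[idx]
        stack.power.append(power)
        stack.times.append(t0 + centers / fs)
        stack.valid.append(valid)
        stack.half_n.append(half)
        stack.center_idx.append(centers)
    return stack


def wavelet_coefficients(data: np.ndarray, fs: float, k: int,
                         grid: FrequencyGrid | None = None) -> np.ndarray:
    """Complex Morlet coefficients at grid frequency ``k`` (windowed, subsampled).

    The transform is linear in the input; power envelopes are the squared
    magnitude of these coefficients.
    """
    if grid is None:
        grid = make_grid()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    w = _morlet(grid.centers[k], grid.sigma_t[k], fs)
    step_n = max(1, int(round(grid.step_s[k] * fs)))
    coef = signal.oaconvolve(data, np.conj(w[::-1])[None, :], mode="valid", axes=1)
    return coef[:, ::step_n]


def window_average(x: np.ndarray, stack: EnvelopeStack, k: int) -> np.ndarray:
    """Average a companion series over each wavelet window support at frequency k.

    This is the downsampling applied to the pupil trace before pairing it with
    a power envelope: the mean of ``x`` over the +-3 sigma_t support of each
    analysis window.
    """
    x = np.asarray(x, float)
    half = stack.half_n[k]
    idx = stack.center_idx[k]
    c = np.concatenate(([0.0], np.cumsum(x)))
    lo = idx - half
    hi = idx + half + 1
    return (c[hi] - c[lo]) / (hi - lo)


@dataclass
class SegmentedSpectra:
    """Per-segment Welch spectra paired with segment-mean pupil values.

    ``psd`` has shape (n_segments, n_channels, n_freqs) in power/Hz units;
    ``seg_pupil`` is the pupil mean over each (forward-shifted) segment window,
    ``seg_pupil_deriv`` the unshifted derivative mean.
    """

    freqs: np.ndarray
    psd: np.ndarray
    seg_t: np.ndarray
    seg_pupil: np.ndarray
    seg_pupil_deriv: np.ndarray
    seg_len_s: float
    shift_s: float


def segment_spectra(
    neural: np.ndarray,
    fs: float,
    pupil: np.ndarray,
    pupil_deriv: np.ndarray | None = None,
    seg_len_s: float = 2.0,
    shift_s: float = 0.93,
    f_range: tuple[float, float] = (2.0, 128.0),
    overlap: float = 0.0,
    min_segments: int = 14,
) -> SegmentedSpectra:
    """Segment-wise power spectra with pupil pairing.

    Each segment of length ``seg_len_s`` is Hann-tapered as a single window
    (frequency resolution = 1/seg_len_s, i.e. 0.5 Hz for 2-s segments).  The
    pupil value assigned to a segment is its mean over the segment window
    shifted *forward* by ``shift_s`` (930 ms by default), compensating the lag
    of the peripheral pupil apparatus; the pupil derivative is averaged without
    a shift.  Segments whose (shifted) window extends past either recording are
    dropped.
    """
    neural = np.atleast_2d(np.asarray(neural, float))
    pupil = np.asarray(pupil, float)
    n_ch, n = neural.shape
    seg_n = int(round(seg_len_s * fs))
    hop = max(1, int(round(seg_n * (1.0 - overlap))))
    shift_n = int(round(shift_s * fs))
    starts = []
    for s0 in range(0, n - seg_n + 1, hop):
        p0 = s0 + shift_n
        if p0 < 0 or p0 + seg_n > len(pupil):
            continue
        starts.append(s0)
    if len(starts) < min_segments:
        raise ValueError(
            f"only {len(starts)} usable segments (< {min_segments}); recording too short"
        )
    starts = np.asarray(starts)
    freqs_full = np.fft.rfftfreq(seg_n, 1.0 / fs)
    sel = (freqs_full >= f_range[0] - 1e-9) & (freqs_full <= f_range[1] + 1e-9)
    win = signal.windows.hann(seg_n, sym=False)
    scale = 2.0 / (fs * np.sum(win ** 2))
    psd = np.empty((len(starts), n_ch, int(sel.sum())))
    seg_pupil = np.empty(len(starts))
    seg_deriv = np.empty(len(starts))
    for i, s0 in enumerate(starts):
        seg = neural[:, s0:s0 + seg_n] * win
        spec = np.abs(np.fft.rfft(seg, axis=1)) ** 2 * scale
        # one-sided density: halve DC/Nyquist double-count
        if freqs_full[0] == 0:
            spec[:, 0] /= 2.0
        if seg_n % 2 == 0:
            spec[:, -1] /= 2.0
        psd[i] = spec[:, sel]
        p0 = s0 + shift_n
        seg_pupil[i] = pupil[p0:p0 + seg_n].mean()
        if pupil_deriv is not None:
            seg_deriv[i] = pupil_deriv[s0:s0 + seg_n].mean()
        else:
            seg_deriv[i] = np.nan
    return SegmentedSpectra(
        freqs=freqs_full[sel],
        psd=psd,
        seg_t=starts / fs,
        seg_pupil=seg_pupil,
        seg_pupil_deriv=seg_deriv,
        seg_len_s=seg_len_s,
        shift_s=shift_s,
    )


def band_power(spectra: SegmentedSpectra, grid: FrequencyGrid | None = None,
               log: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment power at each grid center, averaged over its half-octave band.

    Returns (centers_used, power[segments, channels, centers]).
    """
    if grid is None:
        grid = make_grid()
    f = spectra.freqs
    cols = []
    centers = []
    for k in range(grid.n_freqs):
        sel = (f >= grid.band_lo[k]) & (f <= grid.band_hi[k])
        if not sel.any():
            warnings.warn(f"no PSD bins in band around {grid.centers[k]:.2f} Hz; skipped")
            continue
        p = spectra.psd[:, :, sel].mean(axis=2)
        cols.append(np.log10(p) if log else p)
        centers.append(grid.centers[k])
    return np.asarray(centers), np.stack(cols, axis=2)
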