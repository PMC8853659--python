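"""Synthetic pupil + neural recordings with known ground-truth coupling.

The generator emulates the statistical structure of concurrent resting-state
pupillometry and multichannel electrophysiology:

* a slow pupil process band-limited to 0.005-2 Hz with a narrowband Hippus
  component near 0.2 Hz, blink gaps with biphasic recovery deflections, and
  saccade-locked transients;
* neural channels composed of a 1/f^chi aperiodic background whose exponent
  can covary with pupil, plus band-limited oscillations whose amplitude
  envelopes couple to the (lagged) pupil linearly and/or quadratically.

Every dataset carries a serializable :class:`GroundTruth` manifest; recovery
tests read expected values from the manifest only.

Lag convention: a coupling with ``lag_s = L`` modulates the envelope with
``z(t - L)``, i.e. negative L means the neural envelope *leads* the pupil
(cross-correlogram peak at tau = -L under the analysis convention that
positive lags mean neural activity precedes the pupil).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "BandCoupling", "GroundTruth", "PupilSim", "NeuralSim", "SyntheticSubject",
    "generate_pupil", "generate_neural", "filtered_zpupil", "make_subject",
    "preset_ground_truth", "PRESETS",
]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class BandCoupling:
    """Envelope-pupil coupling of one oscillation band in one channel group."""

    group: str               # "anterior", "posterior" or "all"
    center_hz: float
    gain: float = 0.0        # linear envelope gain per unit z-pupil
    quad: float = 0.0        # quadratic coefficient (negative = inverted U)
    lag_s: float = 0.0       # envelope follows z(t - lag)
    snr: float = 1.0         # oscillation RMS relative to same-band background


@dataclass
class GroundTruth:
    seed: int = 0
    chi0: float = 1.0                 # baseline aperiodic exponent
    exponent_slope: float = 0.0       # d chi per unit z-pupil
    exponent_lag_s: float = 0.93
    hippus_freq_hz: float = 0.2
    hippus_bw_hz: float = 0.06
    hippus_amp: float = 0.35          # Hippus RMS relative to slow-drift RMS
    pupil_chi: float = 1.5            # slow-drift spectral exponent in-band
    blink_rate_hz: float = 0.1
    saccade_rate_hz: float = 1.0
    couplings: list = field(default_factory=list)

    def couplings_for(self, group: str) -> list:
        return [c for c in self.couplings if c.group in (group, "all")]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["couplings"] = [BandCoupling(**c) for c in d.get("couplings", [])]
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Pupil + gaze
# ---------------------------------------------------------------------------

@dataclass
class PupilSim:
    fs: float
    pupil_raw: np.ndarray       # NaN during blinks, artifacts included
    pupil_clean: np.ndarray     # artifact-free slow process (ground truth)
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    blink_intervals: np.ndarray  # (n, 2) start/stop seconds
    saccade_times: np.ndarray

    @property
    def duration_s(self) -> float:
        return len(self.pupil_raw) / self.fs


def _band_limited_noise(n: int, fs: float, band: tuple[float, float],
                        exponent: float, rng: np.random.Generator) -> np.ndarray:
    """FFT-shaped noise: amplitude f^(-exponent/2) inside ``band``, zero outside."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(f)
    sel = (f >= band[0]) & (f <= band[1])
    with np.errstate(divide="ignore"):
        amp[sel] = f[sel] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * amp, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _gamma_kernel(fs: float, t_peak: float, duration: float) -> np.ndarray:
    t = np.arange(0, int(duration * fs)) / fs
    h = (t / t_peak) * np.exp(1.0 - t / t_peak)
    return h


def generate_pupil(
    duration_s: float,
    fs_hz: float = 1000.0,
    hippus_freq_hz: float = 0.2,
    hippus_bw_hz: float = 0.06,
    seed: int | np.random.Generator = 0,
    hippus_amp: float = 0.35,
    blink_rate_hz: float = 0.1,
    saccade_rate_hz: float = 1.0,
    saccade_response_amp: float = 0.08,
    pupil_chi: float = 1.5,
    mean_diameter: float = 5.0,
    diameter_sd: float = 0.5,
) -> PupilSim:
    """Generate a raw pupil trace with gaze, blinks, and saccade transients.

    The clean pupil is an aperiodic drift band-limited to 0.005-2 Hz plus a
    narrowband Hippus component, standardized to ``diameter_sd`` around
    ``mean_diameter`` (arbitrary units).  Blinks are NaN gaps of 100-400 ms
    followed by a biphasic recovery deflection; saccades add small
    canonical-response transients at the recorded gaze-saccade times.
    """
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if duration_s < 60:
        raise ValueError("duration must be at least 60 s")
    if fs_hz < 100:
        raise ValueError("pupil sampling rate must be at least 100 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    slow = _band_limited_noise(n, fs_hz, (0.005, 2.0), pupil_chi, rng)
    clean = slow.copy()
    if hippus_amp > 0 and hippus_freq_hz > 0:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1.0 / fs_hz)
        bump = np.exp(-((f - hippus_freq_hz) ** 2) / (2.0 * (hippus_bw_hz / 2.0) ** 2))
        hip = np.fft.irfft(spec * bump, n)
        hip *= hippus_amp / hip.std()
        clean = clean + hip
    clean = clean / clean.std() * diameter_sd + mean_diameter

    # gaze: slow fixational drift + white tracker noise + ballistic saccades
    drift_x = _band_limited_noise(n, fs_hz, (0.01, 2.0), 1.0, rng) * 0.05
    drift_y = _band_limited_noise(n, fs_hz, (0.01, 2.0), 1.0, rng) * 0.05
    gx = drift_x + rng.standard_normal(n) * 0.01
    gy = drift_y + rng.standard_normal(n) * 0.01
    saccade_times = np.array([])
    if saccade_rate_hz > 0:
        n_sac = rng.poisson(saccade_rate_hz * duration_s)
        saccade_times = np.sort(rng.uniform(1.0, duration_s - 2.0, size=n_sac))
        ramp_n = max(2, int(round(0.02 * fs_hz)))   # 20 ms ballistic profile
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp_n)))
        for ts in saccade_times:
            amp = rng.lognormal(np.log(0.3), 0.5)
            theta = rng.uniform(0, 2 * np.pi)
            i0 = int(round(ts * fs_hz))
            ax, ay = amp * np.cos(theta), amp * np.sin(theta)
            gx[i0:i0 + ramp_n] += ramp * ax
            gy[i0:i0 + ramp_n] += ramp * ay
            gx[i0 + ramp_n:] += ax
            gy[i0 + ramp_n:] += ay

    raw = clean.copy()
    if saccade_response_amp > 0 and len(saccade_times):
        kern = _gamma_kernel(fs_hz, t_peak=0.93, duration=4.0)
        imp = np.zeros(n)
        np.add.at(imp, np.round(saccade_times * fs_hz).astype(int), 1.0)
        raw = raw + signal.fftconvolve(imp, kern)[:n] * (saccade_response_amp * diameter_sd)

    blink_intervals = []
    if blink_rate_hz > 0:
        n_blink = rng.poisson(blink_rate_hz * duration_s)
        starts = np.sort(rng.uniform(1.0, duration_s - 2.0, size=n_blink))
        rec = None
        for ts in starts:
            dur = rng.uniform(0.1, 0.4)
            i0 = int(round(ts * fs_hz))
            i1 = min(n, i0 + int(round(dur * fs_hz)))
            raw[i0:i1] = np.nan
            # biphasic recovery: constriction dip then small dilation overshoot
            if rec is None:
                rec = (-0.5 * _gamma_kernel(fs_hz, 0.1, 2.0)
                       + 0.25 * _gamma_kernel(fs_hz, 0.4, 2.0)) * diameter_sd
            j1 = min(n, i1 + len(rec))
            raw[i1:j1] += rec[: j1 - i1]
            blink_intervals.append((ts, i1 / fs_hz))
    blink_intervals = np.asarray(blink_intervals, float).reshape(-1, 2)
    return PupilSim(fs=fs_hz, pupil_raw=raw, pupil_clean=clean, gaze_x=gx, gaze_y=gy,
                    blink_intervals=blink_intervals, saccade_times=saccade_times)


def filtered_zpupil(pupil_clean: np.ndarray, fs_in: float, fs_out: float,
                    band: tuple[float, float] = (0.005, 2.0)) -> np.ndarray:
    """The z-scored 0.005-2 Hz pupil trace the analysis will see, at ``fs_out``."""
    from .preproc import bandpass_zero_phase
    y = bandpass_zero_phase(np.asarray(pupil_clean, float), fs_in, band)
    if fs_in != fs_out:
        from fractions import Fraction
        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        y = signal.resample_poly(y, frac.numerator, frac.denominator)
    return (y - y.mean()) / y.std()


# ---------------------------------------------------------------------------
# Neural channels
# ---------------------------------------------------------------------------

@dataclass
class NeuralSim:
    fs: float
    data: np.ndarray            # channels x samples
    coords: np.ndarray          # anterior-posterior coordinate (+1 anterior)
    groups: list                # group label per channel


def _lagged(z: np.ndarray, lag_s: float, fs: float) -> np.ndarray:
    """z(t - lag) with edge-hold extrapolation."""
    shift = int(round(lag_s * fs))
    idx = np.clip(np.arange(len(z)) - shift, 0, len(z) - 1)
    return z[idx]


def _aperiodic_background(n: int, fs: float, chi_t: np.ndarray,
                          rng: np.random.Generator,
                          win_s: float = 4.0) -> np.ndarray:
    """1/f^chi(t) noise via FFT amplitude masks in overlapping Hann windows.

    chi_t gives the target exponent per sample; each 50%-overlapping window
    is synthesized with the window-mean exponent and crossfaded (Hann
    overlap-add), so the local spectral slope follows chi_t.
    """
    win_n = int(round(win_s * fs))
    win_n -= win_n % 2
    hop = win_n // 2
    win = signal.windows.hann(win_n, sym=False)
    f = np.fft.rfftfreq(win_n, 1.0 / fs)
    f_safe = np.maximum(f, f[1])
    out = np.zeros(n + win_n)
    for s0 in range(0, n, hop):
        chi = float(np.mean(chi_t[s0:min(s0 + win_n, n)]))
        white = rng.standard_normal(win_n)
        spec = np.fft.rfft(white)
        amp = f_safe ** (-chi / 2.0)
        amp[0] = 0.0
        x = np.fft.irfft(spec * amp, win_n)
        sd = x.std()
        if sd > 0:
            x /= sd
        out[s0:s0 + win_n] += x * win
    return out[:n]


def _narrowband(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS narrowband noise (oscillation carrier with natural envelope)."""
    x = _band_limited_noise(n, fs, band, 0.0, rng)
    return x


def generate_neural(
    duration_s: float,
    fs_hz: float,
    n_channels: int,
    ground_truth: GroundTruth,
    zpupil: np.ndarray,
    seed: int | np.random.Generator = 0,
    background_rms: float = 1.0,
    saccade_times: np.ndarray | None = None,
    suppression: dict | None = None,
) -> NeuralSim:
    """Generate coupled multichannel neural time series.

    Each channel is a 1/f^chi(t) background with
    chi(t) = chi0 + exponent_slope * z(t - exponent_lag), plus, per coupling
    defined for the channel's group, a half-octave narrowband oscillation
    whose instantaneous amplitude is
    baseline * max(0, 1 + gain*z(t-lag) + quad*z(t-lag)^2).

    ``suppression`` optionally injects saccade-locked amplitude suppression:
    a dict with keys ``band`` (Hz tuple), ``depth`` (0-1) and ``window_s``
    (start/stop seconds after each saccade); oscillations with centers in
    the band are damped inside the window.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    z = np.asarray(zpupil, float)
    if len(z) < n:
        raise ValueError("zpupil shorter than the requested neural duration")
    z = z[:n]
    for c in ground_truth.couplings:
        if not (2.0 <= c.center_hz <= 128.0):
            raise ValueError(f"band center {c.center_hz} Hz outside [2, 128]")
        if abs(c.lag_s) >= duration_s:
            raise ValueError("coupling lag exceeds recording duration")
    if abs(ground_truth.exponent_lag_s) >= duration_s:
        raise ValueError("exponent lag exceeds recording duration")
    coords = np.linspace(1.0, -1.0, n_channels)
    groups = ["anterior" if c > 0 else "posterior" for c in coords]
    chi_t_base = ground_truth.chi0 + ground_truth.exponent_slope * _lagged(
        z, ground_truth.exponent_lag_s, fs_hz)
    sup_pulse = None
    if suppression is not None and saccade_times is not None and len(saccade_times):
        sup_pulse = np.zeros(n)
        w0, w1 = suppression.get("window_s", (0.0, 0.3))
        for ts in saccade_times:
            i0 = int(round((ts + w0) * fs_hz))
            i1 = int(round((ts + w1) * fs_hz))
            sup_pulse[max(0, i0):min(n, i1)] = 1.0
        # soften edges over ~25 ms so the suppression is not a hard gate
        k = max(1, int(round(0.025 * fs_hz)))
        sup_pulse = np.convolve(sup_pulse, np.ones(k) / k, mode="same")
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        bg = _aperiodic_background(n, fs_hz, chi_t_base, rng) * background_rms
        x = bg.copy()
        for cpl in ground_truth.couplings_for(groups[ch]):
            band = (cpl.center_hz * 2 ** -0.25, cpl.center_hz * 2 ** 0.25)
            carrier = _narrowband(n, fs_hz, band, rng)
            # oscillation amplitude is defined relative to the *instantaneous*
            # background RMS in its band, so that exponent modulation leaves
            # the periodic (residual) structure invariant: slope and envelope
            # couplings are independent dials
            if ground_truth.exponent_slope == 0.0:
                sel_rms = _band_rms_power_law(band, ground_truth.chi0, fs_hz)
            else:
                chi_grid = np.linspace(chi_t_base.min(), chi_t_base.max(), 33)
                g = np.array([_band_rms_power_law(band, c, fs_hz) for c in chi_grid])
                sel_rms = np.interp(chi_t_base, chi_grid, g)
            amp0 = cpl.snr * background_rms * sel_rms
            zl = _lagged(z, cpl.lag_s, fs_hz)
            mod = np.maximum(1.0 + cpl.gain * zl + cpl.quad * zl ** 2, 0.0)
            osc = amp0 * mod * carrier
            if sup_pulse is not None and suppression is not None:
                lo, hi = suppression.get("band", (8.0, 32.0))
                if lo <= cpl.center_hz <= hi:
                    depth = suppression.get("depth", 0.5)
                    osc = osc * (1.0 - depth * sup_pulse)
            x += osc
        data[ch] = x
    return NeuralSim(fs=fs_hz, data=data, coords=coords, groups=groups)


def _band_rms_power_law(band: tuple[float, float], chi: float, fs: float,
                        win_s: float = 4.0) -> float:
    """RMS fraction of the synthesized unit-RMS 1/f^chi background inside ``band``.

    Evaluated on the discrete rfft grid of the synthesis window so that the
    fraction matches what :func:`_aperiodic_background` actually produces.
    """
    win_n = int(round(win_s * fs))
    win_n -= win_n % 2
    f = np.fft.rfftfreq(win_n, 1.0 / fs)
    f_safe = np.maximum(f, f[1])
    p = f_safe ** (-chi)
    p[0] = 0.0
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.sqrt(p[sel].sum() / p.sum()))


# ---------------------------------------------------------------------------
# Subjects and presets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSubject:
    ground_truth: GroundTruth
    pupil: PupilSim
    neural: NeuralSim
    suppression: dict | None = None


GRID_CENTERS = {"low": 2.83, "alpha": 9.51, "beta": 11.31, "high": 90.51}

PRESETS = ("null", "linear", "quadratic", "slope", "full")


def preset_ground_truth(name: str, seed: int = 0) -> GroundTruth:
    """Canonical coupling configurations.

    * ``null``: oscillations present, no coupling anywhere (calibration).
    * ``linear``: linear envelope coupling, gain +0.5 at 9.51 Hz with the
      envelope leading the pupil by 930 ms.
    * ``quadratic``: inverted-U coupling (quad -0.5) at 9.51 Hz.
    * ``slope``: aperiodic-exponent coupling only (slope -0.2), uncoupled
      oscillation at 9.51 Hz.
    * ``full``: the qualitative pattern reported for resting cortex — low
      frequencies suppressed, high frequencies enhanced with pupil-linked
      arousal (envelopes leading), opposite-signed alpha coupling anterior
      vs posterior, a posterior inverted U, and a negative exponent slope.
    """
    lo, al, hi = 2.83, 9.51, 90.51
    if name == "null":
        cpl = [BandCoupling("all", al), BandCoupling("all", lo), BandCoupling("all", hi)]
        return GroundTruth(seed=seed, couplings=cpl)
    if name == "linear":
        return GroundTruth(seed=seed, couplings=[
            BandCoupling("all", al, gain=0.5, lag_s=-0.93)])
    if name == "quadratic":
        # carrier centered in 8-16 Hz so the z^2 modulation sidebands
        # (bandwidth up to 4 Hz) stay inside the band
        return GroundTruth(seed=seed, couplings=[
            BandCoupling("all", 11.31, quad=-0.5, lag_s=0.0)])
    if name == "slope":
        return GroundTruth(seed=seed, exponent_slope=-0.2, couplings=[
            BandCoupling("all", al)])
    if name == "full":
        return GroundTruth(seed=seed, exponent_slope=-0.1, couplings=[
            BandCoupling("all", lo, gain=-0.3, lag_s=-0.83),
            BandCoupling("posterior", al, gain=0.3, quad=-0.3, lag_s=-0.21),
            BandCoupling("anterior", al, gain=-0.3, lag_s=-1.0),
            BandCoupling("all", hi, gain=0.3, lag_s=-0.56),
        ])
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")


def make_subject(
    ground_truth: GroundTruth | str,
    duration_s: float = 300.0,
    n_channels: int = 8,
    fs_neural: float = 400.0,
    fs_eye: float = 1000.0,
    seed: int | None = None,
    suppression: dict | None = None,
) -> SyntheticSubject:
    """Generate one synthetic subject (pupil + gaze + neural + manifest)."""
    if isinstance(ground_truth, str):
        ground_truth = preset_ground_truth(ground_truth, seed=seed or 0)
    if seed is None:
        seed = ground_truth.seed
    rng = np.random.default_rng(seed)
    pupil = generate_pupil(
        duration_s, fs_eye,
        hippus_freq_hz=ground_truth.hippus_freq_hz,
        hippus_bw_hz=ground_truth.hippus_bw_hz,
        hippus_amp=ground_truth.hippus_amp,
        blink_rate_hz=ground_truth.blink_rate_hz,
        saccade_rate_hz=ground_truth.saccade_rate_hz,
        pupil_chi=ground_truth.pupil_chi,
        seed=rng,
    )
    z = filtered_zpupil(pupil.pupil_clean, fs_eye, fs_neural)
    neural = generate_neural(
        duration_s, fs_neural, n_channels, ground_truth, z, seed=rng,
        saccade_times=pupil.saccade_times, suppression=suppression,
    )
    return SyntheticSubject(ground_truth=ground_truth, pupil=pupil, neural=neural,
                            suppression=suppression)
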