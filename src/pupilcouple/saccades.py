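"""Microsaccade detection and event-locked spectral changes (control analysis).

Microsaccades are detected from 2-D gaze with the classic velocity-threshold
algorithm: gaze velocity is estimated with a 5-point moving-window
differentiator, a robust (median-based) noise scale eta is computed per
axis, and samples whose velocity exceeds an ellipse with semi-axes
lambda * eta for at least a minimum duration are events.

Event-locked spectral power and pupil size are expressed as percent change
relative to a pre-event baseline bin, quantifying transient oculomotor
effects that could confound slow pupil-power coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["MicrosaccadeEvents", "detect_microsaccades", "event_locked_power",
           "EventLockedResult"]


@dataclass
class MicrosaccadeEvents:
    onsets: np.ndarray          # seconds
    durations: np.ndarray       # seconds
    peak_velocity: np.ndarray   # gaze units / s
    amplitude: np.ndarray       # gaze units (net displacement)

    def __len__(self) -> int:
        return len(self.onsets)


def _velocity(x: np.ndarray, fs: float) -> np.ndarray:
    """5-point moving-window differentiation."""
    v = np.zeros_like(x)
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) * (fs / 6.0)
    if len(x) > 4:
        v[:2] = v[2]
        v[-2:] = v[-3]
    return v


def detect_microsaccades(
    gaze_xy: np.ndarray,
    fs: float,
    lam: float = 6.0,
    min_dur_samples: int = 5,
    merge_gap_s: float = 0.020,
) -> MicrosaccadeEvents:
    """Velocity-threshold microsaccade detection on monocular gaze.

    ``gaze_xy``: (n, 2) horizontal/vertical gaze.  The per-axis noise scale
    is eta = sqrt(median(v^2) - median(v)^2); an event requires
    (vx/(lam*eta_x))^2 + (vy/(lam*eta_y))^2 > 1 for at least
    ``min_dur_samples`` consecutive samples.  Candidate events closer than
    ``merge_gap_s`` are merged.
    """
    g = np.asarray(gaze_xy, float)
    if g.ndim != 2 or g.shape[1] != 2:
        raise ValueError("gaze_xy must be (n, 2)")
    vx = _velocity(g[:, 0], fs)
    vy = _velocity(g[:, 1], fs)
    eta = []
    for v in (vx, vy):
        e2 = np.median(v ** 2) - np.median(v) ** 2
        eta.append(np.sqrt(max(e2, 0.0)))
    if eta[0] == 0 or eta[1] == 0:
        return MicrosaccadeEvents(*(np.empty(0),) * 4)  # constant gaze
    crit = (vx / (lam * eta[0])) ** 2 + (vy / (lam * eta[1])) ** 2 > 1.0
    # candidate runs of super-threshold samples
    d = np.diff(crit.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if crit[0]:
        starts.insert(0, 0)
    if crit[-1]:
        stops.append(len(crit))
    runs = list(zip(starts, stops))
    # merge runs separated by less than merge_gap_s
    gap = int(round(merge_gap_s * fs))
    merged = []
    for s0, s1 in runs:
        if merged and s0 - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], s1)
        else:
            merged.append((s0, s1))
    keep = [(s0, s1) for s0, s1 in merged if s1 - s0 >= min_dur_samples]
    onsets = np.array([s0 / fs for s0, _ in keep])
    durations = np.array([(s1 - s0) / fs for s0, s1 in keep])
    speed = np.sqrt(vx ** 2 + vy ** 2)
    pv = np.array([speed[s0:s1].max() for s0, s1 in keep])
    amp = np.array([np.hypot(g[s1 - 1, 0] - g[s0, 0], g[s1 - 1, 1] - g[s0, 1])
                    for s0, s1 in keep])
    return MicrosaccadeEvents(onsets, durations, pv, amp)


@dataclass
class EventLockedResult:
    freqs: np.ndarray
    bin_centers: np.ndarray
    pct_power: np.ndarray       # channels x freqs x bins, percent change
    pct_pupil: np.ndarray | None
    n_events_used: int
    n_events_dropped: int
    baseline_bin: int


def event_locked_power(
    neural: np.ndarray,
    fs: float,
    event_onsets: np.ndarray,
    window_s: float = 0.5,
    step_s: float = 0.05,
    t_range: tuple[float, float] = (-0.5, 2.0),
    baseline_center_s: float = -0.25,
    pupil: np.ndarray | None = None,
    min_events: int = 10,
) -> EventLockedResult:
    """Percent change of spectral power (and pupil) around events.

    Sliding Hann-tapered windows of ``window_s`` stepped by ``step_s`` tile
    the peri-event range; per window a single-taper power spectrum is
    computed and averaged over events, then expressed as percent change
    relative to the bin centered at ``baseline_center_s``.  Pupil values are
    Hann-weighted window sums treated the same way.  Events without full
    peri-event coverage are dropped.
    """
    y = np.atleast_2d(np.asarray(neural, float))
    n_ch, n = y.shape
    win_n = int(round(window_s * fs))
    centers = np.arange(t_range[0] + window_s / 2, t_range[1] - window_s / 2 + 1e-9,
                        step_s)
    base_bin = int(np.argmin(np.abs(centers - baseline_center_s)))
    win = signal.windows.hann(win_n, sym=False)
    onsets = np.asarray(event_onsets, float)
    used, dropped = [], 0
    for te in onsets:
        i0 = int(round((te + centers[0] - window_s / 2) * fs))
        i1 = int(round((te + centers[-1] + window_s / 2) * fs))
        if i0 < 0 or i1 > n:
            dropped += 1
        else:
            used.append(te)
    if len(used) < min_events:
        raise ValueError(f"only {len(used)} events with full coverage (< {min_events})")
    freqs = np.fft.rfftfreq(win_n, 1.0 / fs)
    power = np.zeros((n_ch, len(freqs), len(centers)))
    pupil_sum = np.zeros(len(centers)) if pupil is not None else None
    for te in used:
        for b, c in enumerate(centers):
            s0 = int(round((te + c - window_s / 2) * fs))
            seg = y[:, s0:s0 + win_n] * win
            power[:, :, b] += np.abs(np.fft.rfft(seg, axis=1)) ** 2
            if pupil is not None:
                pupil_sum[b] += np.sum(pupil[s0:s0 + win_n] * win)
    power /= len(used)
    base = power[:, :, base_bin][:, :, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * (power - base) / base
    pct_pupil = None
    if pupil is not None:
        pupil_mean = pupil_sum / len(used)
        pct_pupil = 100.0 * (pupil_mean - pupil_mean[base_bin]) / abs(pupil_mean[base_bin])
    return EventLockedResult(freqs=freqs, bin_centers=centers, pct_power=pct,
                             pct_pupil=pct_pupil, n_events_used=len(used),
                             n_events_dropped=dropped, baseline_bin=base_bin)
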