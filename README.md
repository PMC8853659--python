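# pupilcouple

Frequency-resolved coupling between pupil-linked arousal and neural
population activity.

Spontaneous fluctuations in pupil diameter, recorded under constant
illumination, track the activity of subcortical neuromodulatory systems
(locus coeruleus / basal forebrain) and are widely used as a peripheral
readout of cortical arousal state. `pupilcouple` implements a complete,
tested analysis pipeline for concurrent resting-state pupillometry and
multichannel electrophysiology (MEG/EEG sensor or source time series):

* **Pupil preprocessing** — blink detection and interpolation, removal of
  canonical blink/saccade responses (gamma kernel peaking at 930 ms),
  zero-phase 0.005–2 Hz band-pass, 400 Hz analysis rate, first derivative.
* **Spectral estimates** — Morlet wavelet power envelopes
  `Y(t,f) = |X(t,f)|²` on 25 log-spaced center frequencies (2–128 Hz,
  half-octave bands, 80 % window overlap), and 2-s Welch segments at 0.5 Hz
  resolution paired with forward-shifted (930 ms) segment-mean pupil.
* **Coupling measures** — Gaussian-copula mutual information
  `I = −½·log₂(1−ρ²)` standardized against 200 circular time-shift
  surrogates (±10 s guard); lagged cross-correlation `r(τ)` over ±10 s
  (positive τ = cortex precedes pupil) with anterior→posterior channel
  binning; Spearman maps of power against the 930-ms-shifted pupil.
* **Aperiodic parameterization** — per-segment decomposition of the 3–40 Hz
  spectrum into `offset − χ·log₁₀f` plus ≤6 Gaussian peaks; exponent–pupil
  correlation and residual ("periodic-only") band-power coupling.
* **Inverted-U models** — 14 equidistant pupil bins, z-scored bin means,
  quadratic fit `P = β₀ + β₁x + β₂x²`; β₂ < 0 indicates the Yerkes–Dodson
  inverted U, tested against zero across subjects with BH-FDR (q = 0.1).
* **Microsaccade control** — velocity-threshold detection (λ = 6, ≥5
  samples ≙ 12.5 ms) and event-locked percent change of power and pupil.
* **Synthetic data generator** — pupil traces with a Hippus component near
  0.2 Hz, blinks and saccades, plus neural channels with a 1/f^χ background
  whose exponent covaries with pupil and band-limited oscillations whose
  envelopes couple linearly or quadratically to the (lagged) pupil, with a
  serializable ground-truth manifest for end-to-end parameter recovery.

## Worked example

```python
import numpy as np
from pupilcouple import synth, preproc, spectral, coupling

# one synthetic subject: alpha envelope leads the pupil by 930 ms (gain 0.5)
sub = synth.make_subject("linear", duration_s=300, n_channels=4, seed=1)

trace = preproc.preprocess_pupil(sub.pupil.pupil_raw, sub.pupil.fs,
                                 saccade_times=sub.pupil.saccade_times)
n = min(len(trace.diameter), sub.neural.data.shape[1])
stack = spectral.wavelet_envelopes(sub.neural.data[:, :n], sub.neural.fs)

mi = coupling.mi_with_surrogates(trace.diameter[:n], stack, seed=1)
xc = coupling.xcorr_lagged(trace.diameter[:n], stack)
k = int(np.argmin(np.abs(stack.grid.centers - 9.51)))
print(f"MI z at 9.51 Hz : {np.mean(mi.mi_z[:, k]):.2f}")
print(f"peak lag        : {np.median(xc.peak_lag_s[:, k]):+.3f} s")
print(f"peak r          : {np.mean(xc.peak_r[:, k]):+.3f}")
```

prints

```
MI z at 9.51 Hz : 2.19
peak lag        : +0.978 s
peak r          : +0.356
```

The standardized MI at the injected frequency sits above its null
(mean z ≈ 0 under zero coupling), and the cross-correlogram peaks near
+0.93 s — positive lag, i.e. the cortical envelope precedes the pupil by
the injected 930 ms, recovered to within one envelope sample (57.7 ms at
this frequency).

The same pipeline runs from the shell:

```bash
pupilcouple synth --preset linear --duration 300 --seed 1 --out subj.h5
pupilcouple mi subj.h5 --out mi.csv
pupilcouple run --seed 7 --out results_dir
```

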