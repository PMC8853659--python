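# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `pupilcouple`. All defaults named here are the package's
analysis settings; every empirical claim below is computed by the test
suite or by `scripts/acceptance.py`.

## Signals and their model

The package analyzes two concurrent streams: a pupil-diameter trace with
horizontal/vertical gaze (eye-tracker rate, typically 1 kHz) and a
multichannel neural recording (analysis rate 400 Hz). Pupil-linked arousal
is treated as a slow latent process visible in the 0.005–2 Hz band of
pupil diameter; its first temporal derivative is carried as a second
arousal readout (in rodents, pupil diameter tracks cholinergic and its
derivative noradrenergic activity more closely). Neural activity is
modeled as an aperiodic 1/f^χ background plus band-limited oscillations;
arousal can couple to the oscillations' amplitude envelopes (linearly or
quadratically, with a lead or lag) and to the aperiodic exponent χ.

## Pupil preprocessing

1. Pupil area, if provided, becomes diameter via d = 2√(a/π).
2. Blink gaps (NaN or sentinel runs) are padded by 150 ms per side and
   linearly interpolated; a second pass interpolates velocity outliers
   (|dx/dt| deviating from the median by more than 16 robust MADs, 50 ms
   pad). Every replaced sample is recorded in `interp_mask`; a fraction
   above 0.5 (configurable) triggers a warning rather than an error,
   since usable recordings with higher blink fractions exist.
3. Canonical responses to blinks and saccades are regressed out. The
   kernel is the gamma-family impulse response h(t) = t^w e^(−t/τ) with
   w = 10.1 and τ chosen so the peak falls at 930 ms, the average latency
   of peak dilation after an arousing event; one amplitude per event type
   is fit by least squares. Blink and saccade kernels share this shape by
   default (both are module parameters).
4. The trace is band-passed to 0.005–2 Hz and resampled to 400 Hz; the
   derivative is a forward difference times the rate, last value repeated.

**Numerical choice — the band-pass.** The pass band is a second-order
Butterworth high-pass/low-pass cascade applied forward and reverse (zero
phase). A 0.005 Hz corner is ~10⁻⁵ of a kHz sampling rate; recursive
biquads there are numerically degenerate in double precision (poles
indistinguishable from +1; we measured passband errors of tens of percent
and transients outlasting entire recordings). The filter is therefore
applied spectrally: the exact squared Butterworth magnitude — what the
forward-reverse pass realizes — multiplies the FFT of a reflection-padded,
mean-removed trace. The response is identical by construction; only the
edge behavior differs (reflection instead of an ill-conditioned recursion).
A second application of the full chain re-attenuates the transition bands,
so preprocessing is idempotent only up to ~1 % near the corners.

## Pupil spectrum and Hippus

The z-scored trace is analyzed with DPSS multitapers (±0.035 Hz spectral
smoothing, zero-padding to 2¹⁹ samples), evaluated on a log-spaced grid
over 0.005–2 Hz, and parameterized (max 3 peaks, detection threshold 0.5
SD, peak bandwidths 0.1–0.5 Hz). The strongest detected peak is reported
as the Hippus frequency — spontaneous pupil oscillation, typically near
0.2 Hz — together with the pupil spectral exponent. Note that with a
purely relative detection threshold some peak is almost always found even
on featureless spectra; the meaningful false-alarm property, verified in
the tests, is that spurious detections do not concentrate at any
particular frequency.

## Wavelet envelopes

Morlet wavelets w(t,f) ∝ exp(−t²/2σ_t²)·exp(−i2πft) are evaluated at 25
log-spaced centers f_k = 2·2^(k/4) (2–128 Hz). Each frequency's band is
the half-octave around the center, [f·2^(−1/4), f·2^(+1/4)]; σ_t is chosen
so that ±1σ_f spans that band (σ_f = (f·2^(1/4) − f·2^(−1/4))/2,
σ_t = 1/2πσ_f). Wavelets are truncated at ±3σ_t, unit-energy normalized;
window centers step by 20 % of the support (80 % overlap) and define the
envelope time axes. Windows needing samples beyond the recording are
dropped; windows touching masked samples are flagged invalid. Power is the
squared coefficient magnitude, so a sinusoid at a center frequency yields
a flat envelope scaling with amplitude².

For every pairing with an envelope, the pupil is reduced to the same
temporal grid by averaging over each wavelet window's support — the
frequency-specific downsampling of the analysis.

## Coupling measures

**Gaussian-copula MI.** Each series is rank-transformed to uniform,
mapped through the inverse normal CDF, and MI = −½log₂(1−ρ²) bits is
computed from the Pearson correlation of the transformed pair. The
estimator inherits the copula's invariance to monotone marginal
transforms and matches the closed form for bivariate Gaussian inputs to
< 0.01 bits at n = 5·10⁴ (validated over ρ ∈ {0, 0.3, 0.6, 0.9}).

**Time-shift surrogates.** Observed MI is standardized against 200
surrogate MIs obtained by circularly shifting the copula-normalized pupil
by offsets drawn uniformly outside a ±10 s guard window. Circular shifts
preserve the marginal distribution and autocorrelation while destroying
the cross-coupling. z = (log MI_obs − mean log MI_surr)/sd log MI_surr.
Under zero coupling this z is centered (|mean| < 0.1) with ≈5 % exceeding
|z| > 1.96, but its distribution is left-skewed (log of near-zero MI) —
it is calibrated, not Gaussian. A consequence of standardizing *log* MI:
the surrogate spread is the log-χ²₁ scale (sd ≈ 2.2), which caps
attainable z near ~4.5 even for noise-free coupling.

**Lagged cross-correlation.** r(τ) is the Pearson correlation of
power(t) with pupil(t+τ) over ±10 s of lags on the envelope's own grid;
positive τ therefore means cortical power precedes the pupil (matching
the convention that negative lags indicate "pupil preceding"). Peak lag
is the signed extremum within ±5 s, refined below the lag grid by a
3-point parabolic fit around the grid extremum (removing quantization to
the envelope's sample spacing). For cross-site comparison, channels
are sorted anterior→posterior, split into equal-count bins (remainder to
the most posterior bins), and correlograms are averaged within three
bands (2–4, 8–16, 64–128 Hz) after linear interpolation onto the lag
grid of each band's highest frequency.

**Shifted rank maps.** Spearman correlation of each envelope with the
pupil shifted forward by 930 ms (derivative: no shift). By construction
this equals the rank-correlation cross-correlogram evaluated at
τ = +0.93 s — asserted exactly in the tests.

## Aperiodic parameterization

Per 2-s segment (single Hann window, 0.5 Hz resolution), the 3–40 Hz
spectrum is decomposed into L(f) = offset − χ·log₁₀f (knee fixed at zero)
plus at most six Gaussians with heights ≥ 0.05 and bandwidths (2σ)
between 1 and 8 Hz. The fit: least-squares seed on log-log axes; robust
refit on points at or below the seeded curve (positive-clipped residuals
under their 2.5th percentile — in practice all non-peak points);
iterative peak extraction, largest residual first, stopping below
max(0.05, 2·SD); joint bounded refinement of all Gaussians (analytic
Jacobian, trust-region); final aperiodic refit on the peak-subtracted
spectrum. All thresholds are pinned for determinism. Recovery: exact
(< 0.01) on noiseless power laws over χ ∈ [0.5, 3], bias < 0.1 under
single-segment estimation noise, and < 0.02 shift from a compliant peak.

The flattened residual (log spectrum minus aperiodic curve) averaged over
each half-octave band whose center lies in 3–40 Hz gives "periodic-only"
band power; correlating it with segment-mean pupil isolates oscillatory
coupling from exponent coupling. The exponent–pupil correlation is
Pearson by default (Spearman available) — the choice is a convention, not
derivable from first principles.

## Inverted-U (quadratic) models

Segments are sorted by (930-ms-shifted) pupil into 14 equidistant bins
spanning [min, max]; empty bins are excluded (more than 4 is an error).
Bin means are z-scored across bins and fit with P = β₀ + β₁x + β₂x², with
x the per-bin mean pupil, z-scored so β weights are comparable across
subjects and invariant to affine pupil rescaling. β₂ < 0 over the fitted
range is the inverted-U signature. Group inference: per-cell one-sample
two-tailed t-tests of β₂ against zero, BH-FDR at q = 0.1 per map. A
subtlety verified in simulation: because band power is right-skewed and
extreme pupil bins hold fewer segments, z-scoring by the sample SD of bin
means induces a small negative β₂ bias at low frequencies for short
recordings; at the 10-minute recordings the recovery studies use, it is
negligible relative to the FDR threshold.

## Microsaccade control

Gaze velocity is estimated with the 5-point moving-window differentiator;
the per-axis noise scale is η = √(median(v²) − median(v)²), and samples
with (v_x/6η_x)² + (v_y/6η_y)² > 1 for at least 5 consecutive samples are
events (candidates closer than 20 ms are merged — the merging rule is a
package choice). Detection runs at 400 Hz, where five samples equal the
intended 12.5 ms minimum duration; at 1 kHz the same sample count admits
5-ms noise runs. Event-locked spectra use 0.5-s Hann windows stepped by
50 ms over −0.5…2 s; percent change is taken against the bin centered at
−0.25 s (identically zero there by construction), pupil values are
Hann-weighted window sums treated identically.

## Synthetic data generator

The generator is first-class, tested code; its manifest (`GroundTruth`)
serializes every coupling parameter and seeds, and recovery tests read
expected values only from it.

* **Pupil**: FFT-shaped noise, amplitude ∝ f^(−1.5/2) inside 0.005–2 Hz
  and zero outside (a steep, arousal-like spectrum), plus a narrowband
  Hippus component at 0.2 ± 0.03 Hz with RMS 0.35 of the drift. Blinks
  (Poisson, 0.1/s) are 100–400 ms NaN gaps followed by a biphasic
  recovery deflection; saccades (Poisson, 1/s) are 20-ms ballistic gaze
  steps that also trigger small canonical pupil responses.
* **Neural background**: white noise shaped by f^(−χ/2) FFT masks in 4-s
  Hann windows with 50 % overlap-add, so χ(t) = χ₀ + slope·z(t − 0.93 s)
  can follow the pupil; each window is variance-normalized. The
  time-averaged Welch slope over 3–40 Hz reproduces −χ₀ within 0.1.
* **Oscillations**: half-octave narrowband noise (so envelopes fluctuate
  naturally) with instantaneous amplitude
  baseline·max(0, 1 + gain·z(t−lag) + quad·z(t−lag)²), where z is the
  0.005–2 Hz filtered, z-scored pupil — exactly what the analysis sees.
  The baseline is the oscillation's SNR times the *instantaneous*
  background RMS in its band (band fraction evaluated on the synthesis
  FFT grid): tying it to the momentary background keeps exponent
  modulation and envelope coupling independent dials, so slope-only
  injections leave the residual (periodic) spectrum uncoupled.
* **Defaults**: SNR 1 (oscillation RMS equals same-band background RMS),
  χ₀ = 1, 400 Hz neural / 1 kHz eye rates. Channel coordinates span an
  anterior (+1) to posterior (−1) axis; couplings can target either half.
  Negative coupling lag means the envelope leads the pupil, producing a
  positive cross-correlogram lag.

Presets: `null` (uncoupled oscillations), `linear` (+0.5 gain at 9.51 Hz,
envelope leading by 930 ms), `quadratic` (−0.5 at 11.31 Hz — centered in
8–16 Hz so the up-to-4-Hz sidebands of the z² modulation stay inside the
band), `slope` (exponent slope −0.2), and `full` (low-frequency
suppression, high-frequency enhancement, opposite-signed anterior /
posterior alpha coupling with a posterior inverted U, negative exponent
slope — the qualitative resting-state pattern).

**What the generator does not emulate**: sensor physics and field spread
(channels are statistically independent), realistic eye-tracker noise
beyond blinks/saccades, nonstationary arousal regimes, and any
correlation structure between channels. Passing recovery tests therefore
demonstrates estimator correctness under the generative model, not
robustness to every property of real recordings.

## Validation studies and problem sizes

The studies behind `tests/test_acceptance.py` and `scripts/acceptance.py`
use: 100 seeds × n = 5·10⁴ for the GCMI oracle; 5 subjects × 10 channels
× 25 frequencies × 200 surrogates (5-minute recordings) for the null
calibration; 50 seeds × 8 channels × 10-minute recordings for lag
recovery, where each band's recovered lag is the sensor/frequency mean
of the refined per-correlogram extrema and the tolerance is one envelope
sample of the band's top frequency (7.5 ms at 128 Hz) — note that the
extremum of the *interpolated band-average* correlogram instead carries
a deterministic few-ms offset from linearly interpolating the coarser
low-frequency lag grids; 20 subjects × 10 minutes for the quadratic and
exponent-coupling studies; 500 segments per χ for exponent bias; 20 runs
for microsaccade precision/recall (events at 5× threshold velocity,
10 ms matching tolerance) and suppression-sign recovery; and a 3-subject
full-preset pipeline run executed twice for bit-identical determinism.
Ten-minute recordings are the upper end of the resting-state sessions the
generator emulates; they give the segment counts and effective sample
sizes the recovery tolerances require.

## Known limitations

* The surrogate-standardized MI z is calibrated but skewed; treating it
  as Gaussian beyond |z| ≈ 2 is unsafe, and its magnitude saturates
  logarithmically (see above).
* Aperiodic fits assume a single power law over 3–40 Hz (no knee); knee
  spectra bias χ.
* Cross-correlogram peak precision is limited by the smooth noise floor
  of the correlogram (set by the pupil's autocorrelation time and the
  recording length), roughly one envelope sample at the highest
  frequencies even after sub-sample refinement.
* The binned quadratic model is sensitive to sparse extreme pupil bins on
  short recordings (see the bias note above).
* Group inference treats subjects as exchangeable; no hierarchical or
  site-level modeling.
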