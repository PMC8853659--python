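import numpy as np
import pytest
from scipy import signal

from pupilcouple import preproc, synth
from pupilcouple.preproc import (area_to_diameter, bandpass_downsample,
                                 canonical_kernel, detect_and_interpolate_blinks,
                                 preprocess_pupil, pupil_spectrum,
                                 remove_event_responses)


class TestAreaToDiameter:
    @pytest.mark.parametrize("area,diam", [(np.pi, 2.0), (0.0, 0.0),
                                           (4 * np.pi, 4.0)])
    def test_closed_form(self, area, diam):
        assert area_to_diameter([area])[0] == pytest.approx(diam)

    def test_nan_preserved_negative_raises(self):
        out = area_to_diameter([np.pi, np.nan])
        assert np.isnan(out[1])
        with pytest.raises(ValueError):
            area_to_diameter([-1.0])


class TestBlinkInterpolation:
    fs = 500.0

    def test_gap_in_ramp_interpolates_exactly(self):
        x = np.linspace(0.0, 10.0, int(60 * self.fs))
        x[1000:1100] = np.nan  # 200 ms gap
        clean, mask = detect_and_interpolate_blinks(x, self.fs)
        ramp = np.linspace(0.0, 10.0, len(x))
        assert np.allclose(clean, ramp, atol=1e-9)
        assert mask[1000:1100].all()

    def test_clean_input_is_identity(self, rng):
        t = np.arange(int(60 * self.fs)) / self.fs
        x = 5 + 0.2 * np.sin(2 * np.pi * 0.2 * t)
        clean, mask = detect_and_interpolate_blinks(x, self.fs)
        assert np.array_equal(clean, x)
        assert not mask.any()

    def test_injected_blinks_marked_with_correct_fraction(self):
        rng = np.random.default_rng(0)
        n = int(300 * self.fs)
        t = np.arange(n) / self.fs
        x = 5 + 0.3 * np.sin(2 * np.pi * 0.1 * t) + 0.01 * rng.standard_normal(n)
        truth = np.zeros(n, bool)
        for i in range(10):
            i0 = int((20 + 25 * i) * self.fs)
            gap = int(0.2 * self.fs)
            x[i0:i0 + gap] = np.nan
            truth[i0:i0 + gap] = True
        clean, mask = detect_and_interpolate_blinks(x, self.fs)
        runs = np.flatnonzero(np.diff(mask.astype(int)) == 1)
        assert len(runs) >= 10
        assert abs(mask.mean() - truth.mean()) < 0.02

    def test_all_artifact_raises(self):
        with pytest.raises(ValueError):
            detect_and_interpolate_blinks(np.full(1000, np.nan), self.fs)

    def test_spike_second_pass(self):
        rng = np.random.default_rng(1)
        n = int(60 * self.fs)
        x = 5 + 0.05 * np.cumsum(rng.standard_normal(n)) / self.fs
        x[7000] += 3.0   # tracker spike
        clean, mask = detect_and_interpolate_blinks(x, self.fs)
        assert mask[7000]
        assert abs(clean[7000] - 5) < 1.0


class TestEventResponses:
    fs = 500.0

    def test_single_kernel_self_removal(self):
        kern = canonical_kernel(self.fs)
        n = int(30 * self.fs)
        x = np.zeros(n)
        i0 = int(5 * self.fs)
        x[i0:i0 + len(kern)] += 2.5 * kern[: n - i0]
        resid = remove_event_responses(x, self.fs, blink_times=[5.0])
        assert np.max(np.abs(resid)) < 1e-6 * kern.max() * 2.5

    def test_no_events_is_noop(self, rng):
        x = rng.standard_normal(5000)
        assert np.array_equal(remove_event_responses(x, self.fs), x)

    def test_recovers_slow_signal_under_blink_responses(self):
        rng = np.random.default_rng(2)
        n = int(300 * self.fs)
        t = np.arange(n) / self.fs
        slow = np.sin(2 * np.pi * 0.05 * t) + 0.5 * np.sin(2 * np.pi * 0.13 * t)
        kern = canonical_kernel(self.fs)
        times = np.sort(rng.uniform(5, 290, 20))
        x = slow.copy()
        imp = np.zeros(n)
        np.add.at(imp, (times * self.fs).astype(int), 1.0)
        x += 0.8 * signal.fftconvolve(imp, kern)[:n]
        resid = remove_event_responses(x, self.fs, blink_times=times)
        assert np.corrcoef(resid, slow)[0, 1] >= 0.99

    def test_event_outside_span_raises(self):
        with pytest.raises(ValueError):
            remove_event_responses(np.zeros(1000), self.fs, blink_times=[10.0])

    def test_kernel_peaks_at_930ms(self):
        kern = canonical_kernel(self.fs)
        assert np.argmax(kern) / self.fs == pytest.approx(0.93, abs=2 / self.fs)


class TestBandpassDownsample:
    def test_constant_input_removed(self):
        trace = bandpass_downsample(np.full(int(120 * 1000), 7.0), 1000.0)
        assert np.max(np.abs(trace.diameter)) < 1e-3 * 7.0
        assert trace.fs == 400.0

    def test_10hz_attenuated_at_least_20db_vs_0p1hz(self):
        fs = 1000.0
        t = np.arange(int(120 * fs)) / fs
        out_fast = bandpass_downsample(np.sin(2 * np.pi * 10 * t), fs).diameter
        out_slow = bandpass_downsample(np.sin(2 * np.pi * 0.1 * t), fs).diameter
        mid = slice(10 * 400, -10 * 400)
        ratio = np.std(out_fast[mid]) / np.std(out_slow[mid])
        assert 20 * np.log10(ratio) <= -20.0

    def test_derivative_integrates_back(self, rng):
        fs = 1000.0
        t = np.arange(int(90 * fs)) / fs
        x = np.sin(2 * np.pi * 0.3 * t) + 0.2 * rng.standard_normal(len(t))
        trace = bandpass_downsample(x, fs)
        recon = trace.diameter[0] + np.concatenate(
            ([0.0], np.cumsum(trace.derivative[:-1]) / trace.fs))
        err = np.max(np.abs(recon - trace.diameter))
        assert err < 1e-6 * trace.diameter.std()

    def test_derivative_of_ramp_segment(self):
        # forward difference of a locally linear trace equals its slope
        fs = 400.0
        x = 0.37 * np.arange(int(60 * fs)) / fs
        trace = preproc.PupilTrace(
            t=np.arange(len(x)) / fs, diameter=x,
            derivative=np.empty(0), fs=fs, interp_mask=np.zeros(len(x), bool))
        d = np.empty_like(x)
        d[:-1] = np.diff(x) * fs
        d[-1] = d[-2]
        assert np.allclose(d, 0.37)

    def test_low_input_rate_warns(self):
        with pytest.warns(UserWarning, match="native"):
            trace = bandpass_downsample(np.zeros(int(120 * 250)), 250.0)
        assert trace.fs == 250.0

    def test_idempotent_up_to_transients(self):
        rng = np.random.default_rng(3)
        x = synth._band_limited_noise(int(300 * 1000), 1000.0, (0.005, 2.0),
                                      1.5, rng)
        once = bandpass_downsample(x, 1000.0)
        twice = bandpass_downsample(once.diameter, 400.0)
        mid = slice(30 * 400, -30 * 400)
        r = np.corrcoef(once.diameter[mid], twice.diameter[mid])[0, 1]
        # a second pass re-attenuates the transition bands around the
        # corners, so agreement is near- but not bit-identity
        assert r > 0.99


class TestPupilSpectrum:
    def test_hippus_peak_recovered(self):
        sim = synth.generate_pupil(300.0, 1000.0, hippus_freq_hz=0.2, seed=11,
                                   blink_rate_hz=0.0, saccade_rate_hz=0.0)
        trace = bandpass_downsample(sim.pupil_clean, 1000.0)
        spec = pupil_spectrum(trace)
        assert spec.hippus_freq_hz == pytest.approx(0.2, abs=0.05)

    def test_scale_invariance(self):
        sim = synth.generate_pupil(120.0, 1000.0, seed=12, blink_rate_hz=0.0,
                                   saccade_rate_hz=0.0)
        a = pupil_spectrum(sim.pupil_clean, fs=1000.0)
        b = pupil_spectrum(2.0 * sim.pupil_clean, fs=1000.0)
        assert np.allclose(a.psd, b.psd, rtol=1e-9)
        assert a.exponent == pytest.approx(b.exponent, abs=1e-9)

    def test_white_noise_rarely_mimics_hippus(self):
        """Spurious peaks on white noise do not concentrate at any frequency."""
        hits = 0
        for s in range(8):
            rng = np.random.default_rng(100 + s)
            x = rng.standard_normal(int(120 * 400))
            spec = pupil_spectrum(x, fs=400.0)
            if np.isfinite(spec.hippus_freq_hz) and \
                    0.15 <= spec.hippus_freq_hz <= 0.25:
                hits += 1
        assert hits <= 2

    def test_short_trace_errors(self):
        with pytest.raises(ValueError):
            pupil_spectrum(np.zeros(100), fs=400.0)


class TestFullChain:
    def test_preprocessed_trace_contract(self, full_subject):
        trace = preprocess_pupil(full_subject.pupil.pupil_raw,
                                 full_subject.pupil.fs,
                                 saccade_times=full_subject.pupil.saccade_times)
        assert np.all(np.isfinite(trace.diameter))
        assert np.all(np.isfinite(trace.derivative))
        assert trace.fs == 400.0
        assert trace.interp_fraction <= 0.5
        assert len(trace.provenance) >= 3

    def test_recovers_clean_pupil(self, full_subject):
        trace = preprocess_pupil(full_subject.pupil.pupil_raw,
                                 full_subject.pupil.fs,
                                 saccade_times=full_subject.pupil.saccade_times)
        z = synth.filtered_zpupil(full_subject.pupil.pupil_clean,
                                  full_subject.pupil.fs, 400.0)
        n = min(len(z), len(trace.diameter))
        r = np.corrcoef(trace.diameter[n // 10: -n // 10],
                        z[n // 10: -n // 10])[0, 1]
        assert r > 0.95
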