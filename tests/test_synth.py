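import json

import numpy as np
import pytest
from scipy import signal

from pupilcouple import synth
from pupilcouple.synth import (BandCoupling, GroundTruth, generate_neural,
                               generate_pupil, make_subject,
                               preset_ground_truth)


class TestGroundTruth:
    def test_manifest_roundtrip(self, tmp_path):
        gt = preset_ground_truth("full", seed=3)
        path = tmp_path / "manifest.json"
        gt.to_json(path)
        back = GroundTruth.from_json(path)
        assert back == gt
        # JSON is plain and stable
        d = json.loads(path.read_text())
        assert d["exponent_slope"] == gt.exponent_slope

    def test_group_and_band_independently_settable(self):
        gt = GroundTruth(couplings=[
            BandCoupling("anterior", 9.51, gain=-0.3),
            BandCoupling("posterior", 9.51, gain=0.3, quad=-0.5)])
        ant = gt.couplings_for("anterior")
        post = gt.couplings_for("posterior")
        assert ant[0].gain == -0.3 and ant[0].quad == 0.0
        assert post[0].gain == 0.3 and post[0].quad == -0.5

    def test_presets_all_build(self):
        for name in synth.PRESETS:
            gt = preset_ground_truth(name, seed=0)
            assert isinstance(gt, GroundTruth)
        with pytest.raises(ValueError):
            preset_ground_truth("bogus")


class TestGeneratePupil:
    def test_determinism(self):
        a = generate_pupil(60.0, 250.0, seed=5)
        b = generate_pupil(60.0, 250.0, seed=5)
        assert np.array_equal(a.pupil_raw, b.pupil_raw, equal_nan=True)
        assert np.array_equal(a.gaze_x, b.gaze_x)
        c = generate_pupil(60.0, 250.0, seed=6)
        assert not np.array_equal(c.pupil_raw, a.pupil_raw, equal_nan=True)

    def test_degenerate_settings_give_pure_band_limited_noise(self):
        sim = generate_pupil(120.0, 500.0, hippus_amp=0.0, blink_rate_hz=0.0,
                             saccade_response_amp=0.0, seed=1)
        assert np.all(np.isfinite(sim.pupil_raw))
        f, p = signal.welch(sim.pupil_raw - sim.pupil_raw.mean(), fs=500.0,
                            nperseg=2 ** 14)
        in_band = p[(f > 0) & (f <= 2.5)].sum()
        out_band = p[f > 2.5].sum()
        assert out_band < 0.01 * in_band

    def test_hippus_peak_location_via_periodogram_oracle(self):
        sim = generate_pupil(300.0, 500.0, hippus_freq_hz=0.2, hippus_amp=1.5,
                             blink_rate_hz=0.0, saccade_response_amp=0.0, seed=2)
        f, p = signal.welch(sim.pupil_clean, fs=500.0, nperseg=2 ** 16)
        sel = (f >= 0.05) & (f <= 1.0)
        assert abs(f[sel][np.argmax(p[sel])] - 0.2) <= 0.05

    def test_blinks_are_nan_gaps(self):
        sim = generate_pupil(300.0, 500.0, blink_rate_hz=0.2, seed=3)
        bad = ~np.isfinite(sim.pupil_raw)
        assert bad.any()
        assert len(sim.blink_intervals) > 0
        # gap lengths within the configured 100-400 ms
        durs = sim.blink_intervals[:, 1] - sim.blink_intervals[:, 0]
        assert np.all((durs >= 0.09) & (durs <= 0.45))

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            generate_pupil(-5.0, 500.0)
        with pytest.raises(ValueError):
            generate_pupil(120.0, 0.0)
        with pytest.raises(ValueError):
            generate_pupil(120.0, 50.0)


class TestGenerateNeural:
    def _z(self, n):
        rng = np.random.default_rng(0)
        z = synth._band_limited_noise(n, 400.0, (0.005, 2.0), 1.5, rng)
        return (z - z.mean()) / z.std()

    def test_spectral_contract_slope(self):
        """Welch log-log slope of a zero-coupling channel is -chi0 within 0.1."""
        n = int(300 * 400)
        for chi in (0.5, 1.0, 2.0):
            neu = generate_neural(300.0, 400.0, 1, GroundTruth(chi0=chi),
                                  self._z(n), seed=4)
            f, p = signal.welch(neu.data[0], fs=400.0, nperseg=1600)
            sel = (f >= 3) & (f <= 40)
            slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
            assert abs(slope + chi) < 0.1

    def test_determinism(self):
        n = int(60 * 400)
        z = self._z(n)
        gt = preset_ground_truth("linear", seed=0)
        a = generate_neural(60.0, 400.0, 2, gt, z, seed=9)
        b = generate_neural(60.0, 400.0, 2, gt, z, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_coordinates_span_anterior_posterior(self):
        n = int(60 * 400)
        neu = generate_neural(60.0, 400.0, 6, GroundTruth(), self._z(n), seed=1)
        assert neu.coords[0] == 1.0 and neu.coords[-1] == -1.0
        assert neu.groups[0] == "anterior" and neu.groups[-1] == "posterior"

    def test_lag_exceeding_duration_raises(self):
        n = int(60 * 400)
        gt = GroundTruth(couplings=[BandCoupling("all", 9.51, gain=0.5,
                                                 lag_s=80.0)])
        with pytest.raises(ValueError, match="lag"):
            generate_neural(60.0, 400.0, 1, gt, self._z(n), seed=0)

    def test_band_outside_range_raises(self):
        n = int(60 * 400)
        gt = GroundTruth(couplings=[BandCoupling("all", 150.0)])
        with pytest.raises(ValueError, match="band"):
            generate_neural(60.0, 400.0, 1, gt, self._z(n), seed=0)

    def test_linear_coupling_modulates_band_amplitude(self):
        fs, dur = 400.0, 240.0
        n = int(dur * fs)
        z = self._z(n)
        gt = GroundTruth(couplings=[BandCoupling("all", 9.51, gain=0.8)])
        neu = generate_neural(dur, fs, 1, gt, z, seed=5)
        sos = signal.butter(4, (8.0, 11.31), btype="bandpass", fs=fs,
                            output="sos")
        env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, neu.data[0])))
        # smooth the envelope to the pupil timescale before correlating
        k = int(2 * fs)
        env_s = np.convolve(env, np.ones(k) / k, mode="same")
        r = np.corrcoef(env_s[k:-k], z[k:-k])[0, 1]
        assert r > 0.5


class TestMakeSubject:
    def test_subject_determinism(self):
        a = make_subject("full", duration_s=60.0, n_channels=2, seed=21)
        b = make_subject("full", duration_s=60.0, n_channels=2, seed=21)
        assert np.array_equal(a.neural.data, b.neural.data)
        assert np.array_equal(a.pupil.pupil_raw, b.pupil.pupil_raw,
                              equal_nan=True)

    def test_hdf5_roundtrip(self, tmp_path):
        from pupilcouple.io import load_subject, save_subject
        sub = make_subject("linear", duration_s=60.0, n_channels=2, seed=8)
        path = tmp_path / "s.h5"
        save_subject(path, sub, manifest_path=tmp_path / "s.json")
        back = load_subject(path)
        assert np.array_equal(back.neural.data, sub.neural.data)
        assert np.array_equal(back.pupil.pupil_raw, sub.pupil.pupil_raw,
                              equal_nan=True)
        assert back.ground_truth == sub.ground_truth
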