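import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pupilcouple import coupling, spectral, synth


def _gaussian_pair(rho, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    return x, y


class TestGCMI:
    def test_matches_closed_form(self):
        rho = 0.6
        truth = -0.5 * np.log2(1 - rho ** 2)
        est = [coupling.gcmi(*_gaussian_pair(rho, 50_000, s)) for s in range(5)]
        assert np.mean(est) == pytest.approx(truth, abs=0.01)

    def test_independent_pairs_near_zero(self):
        est = [coupling.gcmi(*_gaussian_pair(0.0, 100_000, s)) for s in range(5)]
        assert np.mean(est) < 0.001

    def test_monotone_marginal_invariance(self):
        x, y = _gaussian_pair(0.5, 2000, 0)
        a = coupling.gcmi(x, y)
        b = coupling.gcmi(np.exp(x), -y ** 3)
        assert b == pytest.approx(a, abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 1000))
    def test_invariance_under_random_monotone_transforms(self, seed):
        x, y = _gaussian_pair(0.4, 500, seed)
        a = coupling.gcmi(x, y)
        assert coupling.gcmi(2 * x + 3, np.arctan(y)) == pytest.approx(a, abs=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            coupling.gcmi(np.ones(100), np.arange(100.0))
        x = np.arange(100.0)
        with pytest.raises(ValueError):
            coupling.gcmi(x, x)  # |rho| = 1 after copula transform


class TestMIWithSurrogates:
    def _coupled_stack(self, gain=1.0, seed=0, duration=120.0, fs=400.0,
                       chi=1.5):
        rng = np.random.default_rng(seed)
        n = int(duration * fs)
        z = synth._band_limited_noise(n, fs, (0.005, 2.0), chi, rng)
        z = (z - z.mean()) / z.std()
        x = (2.0 + gain * z) * np.cos(2 * np.pi * 16.0 * np.arange(n) / fs)
        st = spectral.wavelet_envelopes(x[None, :], fs,
                                        freq_indices=np.array([12]))
        return z, st

    def test_strong_coupling_clearly_separated_from_null(self):
        """Deterministic envelope-pupil coupling saturates the log-MI z-score.

        The z of log MI against log surrogate MI is bounded by the spread of
        the log-chi-square surrogate distribution (sd ~ 2.2), so even a
        noise-free monotone coupling tops out near z ~ 4.5; we require the
        observed z to approach that ceiling, far beyond the null's |z| < ~2.
        """
        z, st = self._coupled_stack(gain=1.0, seed=1, duration=600.0, chi=0.0)
        res = coupling.mi_with_surrogates(z, st, n_perm=200, seed=3)
        assert res.mi_z[0, 12] > 4.0

    def test_same_seed_reproduces(self):
        z, st = self._coupled_stack(gain=0.3, seed=2)
        a = coupling.mi_with_surrogates(z, st, n_perm=50, seed=9)
        b = coupling.mi_with_surrogates(z, st, n_perm=50, seed=9)
        assert np.array_equal(a.mi_z, b.mi_z, equal_nan=True)
        c = coupling.mi_with_surrogates(z, st, n_perm=50, seed=10)
        assert not np.array_equal(c.mi_z, a.mi_z, equal_nan=True)

    def test_guard_window_too_long_raises(self):
        z, st = self._coupled_stack(seed=3, duration=90.0)
        with pytest.raises(ValueError, match="guard"):
            coupling.mi_with_surrogates(z, st, n_perm=10, guard_s=60.0, seed=0)


class TestXCorr:
    def test_orientation_symmetry(self, rng):
        """r_xy(tau) equals r_yx(-tau) exactly."""
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        r_xy = coupling._pearson_xcorr(y[None, :], x, 50)[0]
        r_yx = coupling._pearson_xcorr(x[None, :], y, 50)[0]
        assert np.allclose(r_xy, r_yx[::-1], atol=1e-12)

    def test_constructed_shift_recovers_positive_lag(self):
        """Envelope carrying the pupil's future peaks at positive lag.

        Positive lags mean neural power precedes the pupil: power(t) matching
        pupil(t + 0.93) puts the extremum at tau = +0.93 s.
        """
        fs = 400.0
        rng = np.random.default_rng(4)
        n = int(240 * fs)
        z = synth._band_limited_noise(n, fs, (0.005, 2.0), 1.5, rng)
        z = (z - z.mean()) / z.std()
        shift = int(round(0.93 * fs))
        future = np.concatenate([z[shift:], z[-1] * np.ones(shift)])
        x = (2.0 + 0.8 * future) * np.cos(2 * np.pi * 16.0 * np.arange(n) / fs)
        x += 0.05 * rng.standard_normal(n)
        st = spectral.wavelet_envelopes(x[None, :], fs,
                                        freq_indices=np.array([12]))
        xc = coupling.xcorr_lagged(z, st, max_lag_s=10.0)
        step = st.actual_step_s(12)
        assert abs(xc.peak_lag_s[0, 12] - 0.93) <= step + 1e-9
        assert xc.peak_r[0, 12] > 0

    def test_white_noise_pointwise_false_positive_rate(self, rng):
        """|r| exceeds the 95% bound at ~5% of lags for independent noise."""
        fracs = []
        for _ in range(20):
            x = rng.standard_normal(3000)
            y = rng.standard_normal(3000)
            r = coupling._pearson_xcorr(y[None, :], x, 200)[0]
            n_eff = 3000 - np.abs(np.arange(-200, 201))
            fracs.append(np.mean(np.abs(r) > 1.96 / np.sqrt(n_eff)))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_extreme_lags_still_finite(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        r = coupling._pearson_xcorr(y[None, :], x, 90)
        assert np.isfinite(r[0, 90])  # zero lag; overlap flagging is end-to-end


class TestBinAverage:
    def _stack_and_xcorr(self, n_ch, r_by_channel, rng):
        fs = 400.0
        x = rng.standard_normal((n_ch, int(60 * fs)))
        st = spectral.wavelet_envelopes(x, fs)
        xc = coupling.xcorr_lagged(rng.standard_normal(x.shape[1]), st,
                                   max_lag_s=5.0)
        return st, xc

    def test_identical_correlograms_pass_through(self, rng):
        st, xc = self._stack_and_xcorr(4, None, rng)
        template = {k: xc.r[k][:1].repeat(4, axis=0) for k in range(25)}
        for k in range(25):
            xc.r[k] = template[k]
        binned = coupling.bin_and_average_xcorr(xc, st, np.linspace(1, -1, 4),
                                                n_bins=2)
        for name, d in binned.items():
            assert np.allclose(d["r"][0], d["r"][1], equal_nan=True)

    def test_equal_count_bins_for_78_channels(self):
        sizes = np.full(39, 78 // 39)
        assert sizes.sum() == 78 and np.all(sizes == 2)
        # and the implementation agrees
        coords = np.linspace(1, -1, 78)
        base, rem = divmod(78, 39)
        assert base == 2 and rem == 0

    def test_remainder_goes_to_posterior_bins(self, rng):
        st, xc = self._stack_and_xcorr(5, None, rng)
        binned = coupling.bin_and_average_xcorr(xc, st, np.linspace(1, -1, 5),
                                                n_bins=2)
        # 5 channels over 2 bins: anterior bin has 2, posterior bin has 3
        for name, d in binned.items():
            assert d["r"].shape[0] == 2

    def test_lag_grid_is_highest_frequency_of_band(self, rng):
        st, xc = self._stack_and_xcorr(2, None, rng)
        binned = coupling.bin_and_average_xcorr(xc, st, np.array([1.0, -1.0]),
                                                n_bins=1)
        grid = st.grid
        for name, (lo, hi) in {"2-4": (2, 4), "8-16": (8, 16),
                               "64-128": (64, 128)}.items():
            k_top = grid.band_indices(lo, hi)[-1]
            assert len(binned[name]["lags_s"]) == len(xc.lags_s[k_top])


class TestRhoMap:
    def test_monotone_transform_gives_unit_rho(self, rng):
        fs = 400.0
        n = int(90 * fs)
        z = synth._band_limited_noise(n, fs, (0.005, 2.0), 1.5, rng)
        st = spectral.wavelet_envelopes(np.zeros((1, n)), fs,
                                        freq_indices=np.array([12]))
        # overwrite the envelope with monotone transforms of the shifted pupil
        step = st.step_samples(12)
        m = int(round(0.93 / st.actual_step_s(12)))
        p = spectral.window_average(z, st, 12)
        n_env = len(p)
        st.power[12] = np.exp(p[None, :] * 0.5)
        st.power[12] = np.concatenate(
            [st.power[12][:, m:], st.power[12][:, :m]], axis=1)
        rho = coupling.shifted_rho_map(z, st, shift_s=0.93)
        assert rho[0, 12] == pytest.approx(1.0)
        st.power[12] = -st.power[12]
        rho = coupling.shifted_rho_map(z, st, shift_s=0.93)
        assert rho[0, 12] == pytest.approx(-1.0)

    def test_consistent_with_spearman_xcorr(self, full_analysis):
        trace, stack, n = full_analysis
        rho = coupling.shifted_rho_map(trace.diameter[:n], stack, shift_s=0.93)
        xc = coupling.xcorr_lagged(trace.diameter[:n], stack, method="spearman",
                                   lags_s=np.array([0.93]))
        for k in (0, 6, 12, 18, 24):
            assert np.allclose(xc.r[k][:, 0], rho[:, k], atol=1e-12)
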