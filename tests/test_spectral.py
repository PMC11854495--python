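"""Spectrum estimation, slope fits, fluctuation scaling, consistency laws."""

import numpy as np
import pytest

import rrscope as rr


def white(T, seed, scale=1.0):
    return scale * np.random.default_rng(seed).standard_normal(T)


class TestPowerSpectrum:
    def test_constant_series_has_no_positive_frequency_power(self):
        ps = rr.power_spectrum(np.full(64, 3.7))
        assert np.allclose(ps.power, 0.0, atol=1e-28)

    def test_unit_sinusoid_spikes_at_its_frequency_index(self):
        T, k = 256, 12
        x = np.sin(2 * np.pi * k * np.arange(T) / T)
        ps = rr.power_spectrum(x)
        assert np.argmax(ps.power) == k - 1  # grid starts at f-index 1
        others = np.delete(ps.power, k - 1)
        assert others.max() < 1e-20 * ps.power.max() + 1e-25

    def test_matches_direct_dft_oracle(self):
        """O(T^2) textbook DFT as an independent check, T=64."""
        T = 64
        x = white(T, 9)
        ps = rr.power_spectrum(x)
        t = np.arange(T)
        for f in range(1, T // 2 + 1):
            c = np.sum(x * np.exp(-1j * 2 * np.pi * t * f / T)) / T
            assert abs(ps.power[f - 1] - abs(c) ** 2) < 1e-12

    def test_white_noise_slope_near_zero(self):
        spectra = [rr.power_spectrum(white(4096, s)) for s in range(20)]
        fit = rr.fit_slope(rr.average_spectra(spectra), n_log_bins=12)
        assert abs(fit.slope) < 0.1

    def test_parseval(self):
        x = white(1000, 3) + 0.5
        assert np.sum(rr.dft_power(x)) == pytest.approx(
            np.mean(x ** 2), abs=1e-10)

    def test_hz_axis(self):
        ps = rr.power_spectrum(white(1024, 0), sampling_interval=0.5)
        assert ps.frequencies[0] == pytest.approx(1 / (1024 * 0.5))
        assert ps.frequencies[-1] == pytest.approx(1.0)  # Nyquist = 1 Hz

    def test_nonfinite_rejected(self):
        x = white(64, 1)
        x[3] = np.nan
        with pytest.raises(ValueError):
            rr.power_spectrum(x)


class TestAverageSpectra:
    def test_identity_and_mean(self):
        a = rr.power_spectrum(white(128, 0))
        b = rr.power_spectrum(white(128, 1))
        same = rr.average_spectra([a, a])
        assert np.allclose(same.power, a.power)
        mean = rr.average_spectra([a, b])
        assert np.allclose(mean.power, (a.power + b.power) / 2)
        assert mean.n_trials == 2

    def test_variance_shrinks_like_one_over_n(self):
        bins = np.array([
            [rr.power_spectrum(white(256, 1000 + 50 * g + i)).power
             for i in range(50)]
            for g in range(8)
        ])  # (groups, trials, bins)
        single_var = bins.reshape(-1, bins.shape[-1]).var(axis=0).mean()
        avg_var = bins.mean(axis=1).var(axis=0).mean()
        assert avg_var == pytest.approx(single_var / 50, rel=0.6)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            rr.average_spectra([rr.power_spectrum(white(128, 0)),
                                rr.power_spectrum(white(256, 0))])


class TestFitSlope:
    def test_exact_inverse_f(self):
        f = np.arange(1, 513, dtype=float) / 1024
        ps = rr.PowerSpectrum(frequencies=f, power=1.0 / f, n_trials=1, T=1024)
        fit = rr.fit_slope(ps)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_flat(self):
        f = np.arange(1, 129, dtype=float) / 256
        ps = rr.PowerSpectrum(frequencies=f, power=np.full(128, 2.5),
                              n_trials=1, T=256)
        assert rr.fit_slope(ps).slope == pytest.approx(0.0, abs=1e-12)

    def test_colored_noise_round_trip(self):
        spectra = [rr.power_spectrum(rr.gen_powerlaw_noise(
            rr.NoiseSpec(beta=-0.8, T=2 ** 16, seed=s))) for s in range(50)]
        fit = rr.fit_slope(rr.average_spectra(spectra), n_log_bins=12)
        assert fit.slope == pytest.approx(-0.8, abs=0.05)

    def test_scale_invariance(self):
        x = rr.gen_powerlaw_noise(rr.NoiseSpec(beta=-1.0, T=4096, seed=2))
        f1 = rr.fit_slope(rr.power_spectrum(x), n_log_bins=12)
        f2 = rr.fit_slope(rr.power_spectrum(10.0 * x), n_log_bins=12)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-9)
        assert f2.intercept == pytest.approx(f1.intercept + 2.0, abs=1e-9)

    def test_too_few_bins(self):
        ps = rr.power_spectrum(white(64, 0))
        with pytest.raises(ValueError):
            rr.fit_slope(ps, band=(ps.frequencies[0], ps.frequencies[1]))


class TestDualRegime:
    def test_single_power_law_gives_equal_slopes(self):
        f = np.arange(1, 1025, dtype=float) / 2048
        ps = rr.PowerSpectrum(frequencies=f, power=f ** -1.2, n_trials=1, T=2048)
        low, high = rr.dual_regime_slopes(ps, f_split=0.1)
        assert low.slope == pytest.approx(high.slope, abs=1e-10)
        assert low.slope == pytest.approx(-1.2, abs=1e-10)

    @pytest.mark.parametrize("pair", [(-1.3, -0.5), (-1.09, -1.07)])
    def test_piecewise_round_trip(self, pair):
        bl, bh = pair
        spectra = [rr.power_spectrum(rr.gen_dual_regime_signal(
            rr.NoiseSpec(beta=bl, T=2 ** 16, dt=1.0, seed=s,
                         dual=(bl, bh, 0.01))), sampling_interval=1.0)
            for s in range(30)]
        low, high = rr.dual_regime_slopes(rr.average_spectra(spectra),
                                          f_split=0.01, n_log_bins=12)
        assert low.slope == pytest.approx(bl, abs=0.1)
        assert high.slope == pytest.approx(bh, abs=0.05)

    def test_split_bin_belongs_to_low_regime(self):
        f = np.arange(1, 65, dtype=float) / 64
        ps = rr.PowerSpectrum(frequencies=f, power=np.ones(64), n_trials=1, T=128)
        low, high = rr.dual_regime_slopes(ps, f_split=float(f[9]))
        assert low.band[1] == pytest.approx(f[9])
        assert high.band[0] == pytest.approx(f[10])

    def test_starved_regime_error_names_it(self):
        ps = rr.power_spectrum(white(64, 0))
        with pytest.raises(ValueError, match="low-frequency"):
            rr.dual_regime_slopes(ps, f_split=ps.frequencies[0] * 1.5)


class TestAlphaTheo:
    @pytest.mark.parametrize("beta,expected", [
        (-1.30, 1.15), (-0.41, 0.705), (0.0, 0.5), (-1.0, 1.0), (2.0, 1.5),
    ])
    def test_values(self, beta, expected):
        assert rr.alpha_theo(beta) == pytest.approx(expected, abs=1e-12)


class TestRmsFluctuation:
    def test_iid_noise_scales_flat(self):
        # windows >= 16 keep the sqrt(1 - 1/w) small-sample bias tiny
        alphas = [rr.rms_fluctuation(white(4096, s), [16, 32, 64, 128]).alpha_fit
                  for s in range(20)]
        assert abs(np.mean(alphas)) < 0.05

    def test_linear_ramp_matches_closed_form(self):
        fs = rr.rms_fluctuation(np.arange(4096, dtype=float),
                                [8, 16, 32, 64, 128])
        # a unit ramp's within-window RMS about the window mean is the
        # standard deviation of 0..w-1, i.e. sqrt((w^2 - 1) / 12)
        expected = np.sqrt((fs.window_sizes.astype(float) ** 2 - 1) / 12)
        assert np.allclose(fs.F_values, expected, rtol=1e-10)
        assert fs.alpha_fit == pytest.approx(1.0, abs=0.01)

    def test_random_walk_scales_diffusively(self):
        alphas = [rr.rms_fluctuation(np.cumsum(white(8192, 100 + s)),
                                     [8, 16, 32, 64, 128, 256]).alpha_fit
                  for s in range(20)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.1)

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            rr.rms_fluctuation(white(256, 0), [4, 128])


class TestAutocorrelation:
    def test_constant_series_is_zero(self):
        ac = rr.autocorrelation(np.full(100, 2.0), 10)
        assert np.allclose(ac.values, 0.0)

    def test_sinusoid_tracks_cosine_of_lag(self):
        T = 1024
        x = np.sin(2 * np.pi * 8 * np.arange(T) / T)
        ac = rr.autocorrelation(x, 128)
        expected = 0.5 * np.cos(2 * np.pi * 8 * ac.lags / T)
        # biased estimator tapers with (1 - tau/T)
        taper = 1 - ac.lags / T
        assert np.allclose(ac.values, expected * taper, atol=0.01)

    def test_matches_double_loop_oracle(self):
        x = white(200, 7)
        ac = rr.autocorrelation(x, 20)
        v = x - x.mean()
        for tau in range(21):
            direct = sum(v[t] * v[t + tau] for t in range(200 - tau)) / 200
            assert abs(ac.values[tau] - direct) < 1e-10

    def test_zero_lag_dominates(self):
        ac = rr.autocorrelation(white(500, 1), 100)
        assert np.all(ac.values[0] >= np.abs(ac.values))

    def test_lag_bound(self):
        with pytest.raises(ValueError):
            rr.autocorrelation(white(50, 0), 50)


class TestWienerKhinchin:
    @pytest.mark.parametrize("series", [
        white(1024, 0),
        np.sin(2 * np.pi * 5 * np.arange(512) / 512),
        np.cumsum(white(300, 4)),
    ], ids=["white", "sinusoid", "walk"])
    def test_residual_vanishes(self, series):
        assert rr.wiener_khinchin_residual(series) < 1e-8


class TestSimulatedTraces:
    def test_normal_condition_grid_is_white(self):
        """Single-neuron spectrum of the dense random-coupling grid:
        no resonance, and the low-band slope is flat (white noise)."""
        spec = rr.condition("normal", "grid", 5)
        sweep = rr.noise_sweep(spec, [2.0], list(np.arange(0.5, 5.01, 0.25)),
                               10_000, scope=[0, 1, 2, 3, 4], seed=11, n_reps=3)
        det = rr.detect_rr(sweep, 2.0)
        assert not det.is_resonant
        r = rr.spectral_noise_default(sweep, 2.0)
        ps = rr.neuron_trace_spectrum(spec, 2.0, r, 8192, 50, neuron=0, seed=11)
        fit = rr.fit_slope(ps, rr.low_half_band(ps), n_log_bins=12)
        assert abs(fit.slope) < 0.2

    def test_one_dimensional_quantum_reddens_high_band(self):
        """5-neuron quantum condition: the 1/f-like scaling sits in the
        high-frequency half of the spectrum."""
        spec = rr.condition("quantum", "linear", 5)
        sweep = rr.noise_sweep(spec, [2.0], list(np.arange(0.25, 5.01, 0.25)),
                               10_000, seed=5, n_reps=3)
        r = rr.spectral_noise_default(sweep, 2.0)
        ps = rr.neuron_trace_spectrum(spec, 2.0, r, 8192, 50, neuron=0, seed=5)
        fit = rr.fit_slope(ps, rr.high_half_band(ps), n_log_bins=8)
        assert -1.4 < fit.slope < -0.5
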