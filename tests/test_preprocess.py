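import numpy as np
import pytest

import swallowkit as sk
from swallowkit.errors import (
    ConfigurationError,
    DegenerateSignalError,
    ParameterError,
)
from swallowkit.preprocess import (
    ARModel,
    SplineConfig,
    ar_models_from_json,
    ar_models_to_json,
)


class TestARFit:
    def test_white_noise_selects_low_order(self, rng):
        x = rng.standard_normal(10**5)
        model = sk.fit_ar_noise_model(x, max_order=10)
        assert model.order <= 2
        assert all(abs(c) <= 0.05 for c in model.coeffs)

    def test_ar3_parameter_recovery(self):
        truth = (0.5, -0.3, 0.2)
        x = sk.gen_device_noise(truth, n=10**5, scale=1.0, seed=8)
        model = sk.fit_ar_noise_model(x, max_order=10)
        assert model.order == 3
        np.testing.assert_allclose(model.coeffs, truth, atol=0.05)
        assert model.noise_var == pytest.approx(1.0, rel=0.05)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            sk.fit_ar_noise_model(np.ones(1000), max_order=5)

    def test_overlong_order_rejected(self):
        with pytest.raises(ParameterError):
            sk.fit_ar_noise_model(np.random.default_rng(0).standard_normal(30), 10)


class TestInverseFilter:
    def test_order_zero_is_identity(self, rng):
        x = rng.standard_normal(500)
        model = ARModel(coeffs=(), noise_var=1.0)
        np.testing.assert_array_equal(sk.inverse_filter(x, model), x)

    def test_impulse_response_is_fir_taps(self):
        model = ARModel(coeffs=(0.9,), noise_var=1.0)
        x = np.zeros(5)
        x[0] = 1.0
        out = sk.inverse_filter(x, model)
        np.testing.assert_allclose(out, [1.0, -0.9, 0.0, 0.0, 0.0])

    def test_whitening_of_self_fitted_noise(self):
        x = sk.gen_device_noise((0.5, -0.3, 0.2), n=10**5, seed=13)
        model = sk.fit_ar_noise_model(x, max_order=8)
        y = sk.inverse_filter(x, model)
        for lag in range(1, 6):
            r = np.corrcoef(y[:-lag], y[lag:])[0, 1]
            assert abs(r) < 0.02

    def test_model_json_roundtrip(self):
        models = {"AP": ARModel(coeffs=(0.5, -0.25), noise_var=0.04)}
        back = ar_models_from_json(ar_models_to_json(models))
        assert back["AP"].coeffs == models["AP"].coeffs
        assert back["AP"].noise_var == models["AP"].noise_var


class TestSplineBaseline:
    def test_zero_signal_gives_zero_baseline(self):
        baseline, detrended = sk.spline_baseline(np.zeros(5000), fs=1000.0)
        np.testing.assert_allclose(baseline, 0.0, atol=1e-12)
        np.testing.assert_allclose(detrended, 0.0, atol=1e-12)

    def test_drift_captured_signal_passed(self):
        """0.5 Hz drift lands in the baseline; 50 Hz content passes through."""
        fs = 1000.0
        t = np.arange(10000) / fs
        cfg = SplineConfig()
        drift = np.sin(2 * np.pi * 0.5 * t)
        _, resid = sk.spline_baseline(drift, fs, cfg, channel="SI")
        assert np.sum(resid**2) <= 0.05 * np.sum(drift**2)
        tone = np.sin(2 * np.pi * 50 * t)
        baseline, _ = sk.spline_baseline(tone, fs, cfg, channel="SI")
        assert np.sum(baseline**2) <= 0.05 * np.sum(tone**2)

    def test_reconstruction_is_exact(self, rng):
        x = rng.standard_normal(8000) + np.linspace(0, 3, 8000)
        baseline, detrended = sk.spline_baseline(x, fs=1000.0)
        np.testing.assert_allclose(baseline + detrended, x, rtol=1e-9, atol=1e-9)

    def test_too_short_signal_rejected(self):
        cfg = SplineConfig(f_l_hz={"AP": 400.0, "SI": 400.0})
        with pytest.raises(ParameterError):
            sk.spline_baseline(np.arange(100, dtype=float), fs=1000.0, cfg=cfg)

    def test_knot_count_formula(self):
        cfg = SplineConfig()
        # round(N * f_l / fs) with floor 2
        assert cfg.n_knots(100000, 4000.0, "SI") == round(100000 * 3.77 / 4000)
        assert cfg.n_knots(100000, 4000.0, "AP") == round(100000 * 1.67 / 4000)
        assert cfg.n_knots(100, 4000.0, "AP") == 2


class TestNoiseSigma:
    def test_all_zero_coefficients(self):
        assert sk.estimate_noise_sigma(np.zeros(10)) == 0.0

    def test_forced_median(self):
        assert sk.estimate_noise_sigma(np.array([-0.6745, 0.6745])) == pytest.approx(1.0)

    def test_gaussian_consistency(self, rng):
        est = sk.estimate_noise_sigma(rng.standard_normal(10**5))
        assert 0.97 <= est <= 1.03

    def test_empty_is_error(self):
        with pytest.raises(DegenerateSignalError):
            sk.estimate_noise_sigma(np.array([]))


class TestWaveletDenoise:
    def test_zero_signal_passes_through(self):
        out = sk.wavelet_denoise(np.zeros(4096))
        np.testing.assert_allclose(out, 0.0)

    def test_noise_energy_suppressed(self, rng):
        x = rng.standard_normal(2**15)
        y = sk.wavelet_denoise(x)
        assert np.sum(y**2) <= 0.15 * np.sum(x**2)

    def test_denoising_reduces_mse_to_clean_signal(self, rng):
        from scipy import signal as sps

        fs, n = 1000.0, 2**14
        t = np.arange(n) / fs
        clean = sps.chirp(t, f0=1.0, f1=20.0, t1=t[-1])
        snr_lin = 10 ** (5 / 10)
        noise = rng.standard_normal(n) * np.sqrt(np.mean(clean**2) / snr_lin)
        noisy = clean + noise
        den = sk.wavelet_denoise(noisy)
        assert np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_idempotent_after_first_pass(self, rng):
        from scipy import signal as sps

        t = np.arange(2**13) / 1000.0
        x = sps.chirp(t, 1.0, t[-1], 15.0) + 0.2 * rng.standard_normal(len(t))
        once = sk.wavelet_denoise(x)
        twice = sk.wavelet_denoise(once)
        assert np.sum((twice - once) ** 2) <= 0.01 * np.sum(once**2)

    def test_empty_input_is_error(self):
        with pytest.raises(DegenerateSignalError):
            sk.wavelet_denoise(np.array([]))


class TestPreprocessRecording:
    def test_missing_model_is_configuration_error(self, one_recording):
        rec, _ = one_recording
        with pytest.raises(ConfigurationError):
            sk.preprocess_recording(rec, {"AP": ARModel((), 1.0)})

    def test_pure_noise_recording_nearly_cancelled(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, swallows_per_subject=0)
        subj = sk.SubjectMeta("S0", "female", 30.0)
        rec, _ = sk.gen_recording(spec, subj, seed=21)
        models = sk.baseline_ar_models(spec)
        clean = sk.preprocess_recording(rec, models)
        for name in rec.channels:
            e_in = np.sum(rec.channels[name] ** 2)
            e_out = np.sum(clean.channels[name] ** 2)
            assert e_out <= 0.20 * e_in

    def test_burst_energy_survives_background_dies(self, small_spec, one_recording):
        """Denoising keeps swallow-interval energy and sharpens the contrast.

        Swallow energy is genuinely low-frequency, and coarse-scale wavelet
        atoms have multi-second support, so some burst energy necessarily
        reappears between swallows: the between-swallow floor is graded on
        what denoising can control — broadband noise above the swallow band
        is annihilated, and the burst-to-background power contrast improves
        on every channel.
        """
        from scipy import signal as sps

        rec, truth = one_recording
        models = sk.baseline_ar_models(small_spec)
        mask = np.zeros(rec.n_samples, dtype=bool)
        for seg in truth:
            mask[seg.slice()] = True
        g0, g1 = truth[0].end + 200, truth[1].start - 200  # longest gap
        for name in ("AP", "SI", "SOUND"):
            pre = sk.inverse_filter(rec.channels[name], models[name])
            if name != "SOUND":
                _, pre = sk.spline_baseline(pre, rec.fs, channel=name)
            out = sk.wavelet_denoise(pre)
            # swallow intervals keep at least half their conditioned energy
            assert np.sum(out[mask] ** 2) >= 0.50 * np.sum(pre[mask] ** 2)
            # broadband (>20 Hz) background noise is essentially removed
            f, p_pre = sps.welch(pre[g0:g1], fs=rec.fs, nperseg=2048)
            _, p_out = sps.welch(out[g0:g1], fs=rec.fs, nperseg=2048)
            hi = f > 20.0
            assert p_out[hi].sum() <= 0.05 * p_pre[hi].sum()
            # burst/background contrast never degrades
            contrast_pre = np.mean(pre[mask] ** 2) / np.mean(pre[~mask] ** 2)
            contrast_out = np.mean(out[mask] ** 2) / np.mean(out[~mask] ** 2)
            assert contrast_out >= contrast_pre

    def test_sound_channel_keeps_low_frequencies(self, small_spec):
        """A spline-detrended variant of SOUND differs only below a few Hz."""
        subj = sk.SubjectMeta("S0", "female", 30.0)
        rec, _ = sk.gen_recording(small_spec, subj, seed=31)
        models = sk.baseline_ar_models(small_spec)
        drift = 0.5 * np.sin(
            2 * np.pi * 0.3 * np.arange(rec.n_samples) / rec.fs
        )
        noisy = rec.with_channels(
            {**rec.channels, "SOUND": rec.channels["SOUND"] + drift}
        )
        clean = sk.preprocess_recording(noisy, models)
        sound = clean.channels["SOUND"]
        with_spline, _ = sk.spline_baseline(sound, rec.fs, channel="SI")
        despline = sound - with_spline
        diff = sound - despline  # exactly the spline baseline
        spec_diff = np.abs(np.fft.rfft(diff)) ** 2
        freqs = np.fft.rfftfreq(len(diff), 1 / rec.fs)
        assert spec_diff[freqs > 4.0].sum() <= 0.1 * spec_diff.sum()
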