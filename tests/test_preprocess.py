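"""Zero-phase filtering, powerline handling, impulse removal, whitening."""

import numpy as np
import pytest
from scipy.signal import correlate

from fecgx.preprocess import (PreprocessConfig, center, detect_powerline,
                              notch_powerline, preprocess_pipeline,
                              remove_baseline, remove_impulses, whiten)
from fecgx.synthetic import (DEFAULT_MORPHOLOGY, SynthConfig, synth_aecg,
                             synth_single_ecg)

FS = 500.0


def _sine(freq, dur=20.0, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(int(dur * fs)) / fs)


def _zero_lag_peak(x, y):
    """Lag (samples) of the cross-correlation maximum between x and y."""
    c = correlate(y, x, mode="full")
    return int(np.argmax(c)) - (len(x) - 1)


class TestBaseline:
    def test_zero_in_zero_out(self):
        assert not np.any(remove_baseline(np.zeros(1000), FS))

    @pytest.mark.parametrize("freq", [0.2, 1.0, 30.0])
    def test_residual_matches_analytic_butterworth_response(self, freq):
        # first-order Butterworth |H(f)|^2 = 1/(1+(f/fc)^2); filtfilt applies
        # the magnitude twice, so the high-passed residual of a unit sinusoid
        # has amplitude 1 - |H|^2 (zero phase)
        x = _sine(freq, dur=60.0)
        out = remove_baseline(x, FS, 5.0)
        core = slice(int(10 * FS), int(50 * FS))  # avoid edge transients
        measured = np.sqrt(2.0) * out[core].std()
        expected = 1.0 - 1.0 / (1.0 + (freq / 5.0) ** 2)
        assert measured == pytest.approx(expected, rel=0.05, abs=5e-4)

    def test_passband_tone_preserved(self):
        x = _sine(30.0)
        out = remove_baseline(x, FS)
        core = slice(1000, 9000)
        assert np.abs(out[core] - x[core]).max() < 0.05

    def test_zero_phase(self):
        x = _sine(12.0)
        out = remove_baseline(x, FS)
        assert _zero_lag_peak(x[1000:9000], out[1000:9000]) == 0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            remove_baseline(np.zeros(100), 8.0, cutoff_hz=5.0)


class TestPowerline:
    def test_detects_50(self, rng):
        x = _sine(50.0) + 0.01 * rng.standard_normal(10000)
        assert detect_powerline(x, FS)["freq"] == 50.0

    def test_detects_60(self):
        assert detect_powerline(_sine(60.0), FS)["freq"] == 60.0

    def test_white_noise_none(self, rng):
        assert detect_powerline(rng.standard_normal(10000), FS)["freq"] is None

    def test_notch_attenuates_fundamental(self):
        x = _sine(50.0)
        out = notch_powerline(x, FS, 50.0)
        assert np.sqrt(np.mean(out ** 2)) < 0.1 * np.sqrt(np.mean(x ** 2))

    def test_notch_attenuates_third_harmonic_20db(self):
        x = _sine(150.0)
        out = notch_powerline(x, FS, 50.0)
        atten = 20 * np.log10(np.sqrt(np.mean(out ** 2)) / np.sqrt(np.mean(x ** 2)))
        assert atten <= -20.0

    def test_dc_and_passband_untouched(self):
        dc = np.full(5000, 3.7)
        np.testing.assert_allclose(notch_powerline(dc, FS, 50.0), dc, atol=1e-6)
        x = _sine(10.0)
        out = notch_powerline(x, FS, 50.0)
        core = slice(1000, 9000)
        assert np.abs(out[core] - x[core]).max() < 0.01
        assert _zero_lag_peak(x[core], out[core]) == 0

    def test_harmonic_above_nyquist_skipped(self):
        # fs 260: 3rd harmonic of 50 Hz (150) exceeds Nyquist, must not raise
        x = np.sin(2 * np.pi * 50 * np.arange(2000) / 260.0)
        notch_powerline(x, 260.0, 50.0)


class TestImpulses:
    def test_clean_sinusoid_untouched(self):
        x = _sine(1.0)
        np.testing.assert_array_equal(remove_impulses(x, FS), x)

    def test_clean_ecg_untouched(self):
        x = synth_single_ecg(75.0, 30.0, FS, None, 0.0, seed=5).samples[0]
        np.testing.assert_array_equal(remove_impulses(x, FS), x)

    def test_constant_untouched(self):
        x = np.full(2000, 1.5)
        np.testing.assert_array_equal(remove_impulses(x, FS), x)

    def test_single_large_spike_removed(self):
        clean = _sine(2.0)
        spike = 10.0 * (clean.max() - clean.min())
        x = clean.copy()
        x[5000] += spike
        out = remove_impulses(x, FS)
        assert abs(out[5000] - clean[5000]) < 0.1 * spike

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            remove_impulses(np.zeros(10), FS, window_ms=60.0)


class TestWhitening:
    def test_center_zeroes_channel_means(self, rng):
        x = rng.normal(loc=3.0, size=(4, 5000))
        assert np.abs(center(x).mean(axis=1)).max() < 1e-10

    def test_constant_channel_centers_to_zero(self):
        assert not np.any(center(np.full((1, 100), 2.5)))

    def test_correlated_gaussian_whitens_to_identity(self, rng):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=10_000).T
        xw, model = whiten(center(x))
        emp = xw @ xw.T / xw.shape[1]
        np.testing.assert_allclose(emp, np.eye(2), atol=0.05)
        np.testing.assert_allclose(model.V.T @ model.V, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(model.transform, model.transform.T, atol=1e-10)

    def test_white_input_transform_is_identity(self, rng):
        x = rng.standard_normal((3, 50_000))
        _, model = whiten(center(x))
        np.testing.assert_allclose(model.transform, np.eye(3), atol=0.05)

    def test_duplicated_channel_rejected(self, rng):
        row = rng.standard_normal(1000)
        with pytest.raises(ValueError, match="rank-deficient"):
            whiten(center(np.vstack([row, row])))

    def test_refit_on_whitened_output_is_identity(self, rng):
        x = rng.multivariate_normal([0, 0, 0], np.eye(3) + 0.5, size=20_000).T
        xw, _ = whiten(center(x))
        _, model2 = whiten(xw)
        np.testing.assert_allclose(model2.transform, np.eye(3), atol=0.05)


class TestPipeline:
    def test_pipeline_raises_snr_against_bandlimited_truth(self):
        cfg = SynthConfig(seed=11, n_channels=1)
        aecg, fecg = synth_aecg(cfg)
        maternal = synth_single_ecg(cfg.maternal_hr_bpm, cfg.duration_s, cfg.fs,
                                    DEFAULT_MORPHOLOGY, cfg.hr_jitter_sd,
                                    aecg.meta["maternal_seed"])
        clean = (aecg.meta["channel_gains"][0] * maternal.samples[0]
                 + cfg.fetal_amp_ratio * fecg.samples[0])
        # the clean mixture as seen through the same zero-phase linear stages
        ref = notch_powerline(remove_baseline(clean, cfg.fs), cfg.fs, 50.0)
        ref -= ref.mean()

        def snr(est):
            return 10 * np.log10(np.sum(est ** 2) / np.sum((est - ref) ** 2))

        out, _ = preprocess_pipeline(aecg, PreprocessConfig(whiten=False))
        raw = aecg.samples[0] - aecg.samples[0].mean()
        assert snr(out.samples[0]) > snr(raw)

    def test_noise_free_input_passthrough(self):
        cfg = SynthConfig(duration_s=20.0, n_channels=1, seed=3,
                          noise={"baseline_amp": 0, "powerline_amp": 0,
                                 "powerline_freq_hz": 50, "impulse_rate_per_s": 0,
                                 "impulse_amp": 0, "white_sd": 0})
        aecg, _ = synth_aecg(cfg)
        out, model = preprocess_pipeline(aecg, PreprocessConfig(whiten=False))
        assert model is None
        # only baseline removal and centering act; QRS timing untouched
        det_in = np.argmax(aecg.samples[0][:400])
        det_out = np.argmax(out.samples[0][:400])
        assert det_in == det_out

    def test_single_channel_whitening_gives_unit_variance(self, aecg_pair):
        aecg, _ = aecg_pair
        out, model = preprocess_pipeline(aecg, PreprocessConfig())
        assert model is not None
        assert out.samples[0].std() == pytest.approx(1.0, rel=1e-6)

    def test_pipeline_is_deterministic(self, aecg_pair):
        aecg, _ = aecg_pair
        a, _ = preprocess_pipeline(aecg, PreprocessConfig())
        b, _ = preprocess_pipeline(aecg, PreprocessConfig())
        np.testing.assert_array_equal(a.samples, b.samples)
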