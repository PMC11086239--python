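"""Synthetic generator: beat counts, determinism, noise spectra, mixtures."""

import numpy as np
import pytest
from scipy.signal import periodogram

from fecgx.synthetic import (DEFAULT_MORPHOLOGY, SynthConfig, synth_aecg,
                             synth_noise, synth_single_ecg)


class TestSingleEcg:
    def test_beat_count_matches_rate(self):
        # 120 bpm for 60 s with no jitter: floor(60*120/60) +- 1 annotated beats
        rec = synth_single_ecg(120.0, 60.0, 500.0, None, 0.0, seed=0)
        assert abs(len(rec.r_peaks["self"]) - 120) <= 1

    @pytest.mark.parametrize("hr,dur", [(75.0, 30.0), (140.0, 45.0)])
    def test_annotations_sit_on_r_maxima(self, hr, dur):
        rec = synth_single_ecg(hr, dur, 500.0, None, 2.0, seed=3)
        sig = rec.samples[0]
        for p in rec.r_peaks["self"]:
            lo = max(0, p - 5)
            local = lo + np.argmax(sig[lo:p + 6])
            assert abs(local - p) <= 2

    def test_zero_amplitude_template_gives_zero_signal(self):
        morph = {w: (0.0, b, th) for w, (_, b, th) in DEFAULT_MORPHOLOGY.items()}
        rec = synth_single_ecg(100.0, 10.0, 500.0, morph, 0.0, seed=0)
        assert not np.any(rec.samples)

    def test_same_seed_bit_identical(self):
        a = synth_single_ecg(90.0, 20.0, 500.0, None, 3.0, seed=11)
        b = synth_single_ecg(90.0, 20.0, 500.0, None, 3.0, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.r_peaks["self"], b.r_peaks["self"])

    @pytest.mark.parametrize("kwargs", [
        dict(hr_bpm=20.0), dict(hr_bpm=400.0), dict(duration_s=-1.0),
        dict(fs=0.0), dict(morph_params={}),
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        base = dict(hr_bpm=100.0, duration_s=5.0, fs=500.0,
                    morph_params=None, hr_jitter_sd=0.0, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            synth_single_ecg(**base)


class TestNoise:
    def test_powerline_spectrum_peaks_at_fundamental_and_3rd(self):
        x = synth_noise("powerline", {"powerline_amp": 1.0, "powerline_freq_hz": 50.0},
                        50_000, 500.0, seed=0)
        f, p = periodogram(x, fs=500.0)
        assert abs(f[np.argmax(p)] - 50.0) < 0.5
        p2 = p.copy()
        p2[np.abs(f - 50.0) < 2.0] = 0.0
        assert abs(f[np.argmax(p2)] - 150.0) < 0.5
        # negligible energy away from the two lines
        p2[np.abs(f - 150.0) < 2.0] = 0.0
        assert p2.max() < 1e-6 * p.max()

    def test_zero_amplitude_is_zero_vector(self):
        for kind in ("baseline", "powerline", "impulse", "white"):
            x = synth_noise(kind, {}, 1000, 500.0, seed=1)
            assert not np.any(x)

    def test_impulse_count_near_poisson_mean(self):
        # rate 2/s over 10 s -> ~20 spikes well above the (zero) background
        counts = [np.sum(np.abs(synth_noise(
            "impulse", {"impulse_rate_per_s": 2.0, "impulse_amp": 1.0},
            5000, 500.0, seed=s)) > 0.5) for s in range(5)]
        assert 10 <= np.mean(counts) <= 30

    def test_baseline_energy_below_5hz(self):
        x = synth_noise("baseline", {"baseline_amp": 1.0}, 50_000, 500.0, seed=2)
        f, p = periodogram(x, fs=500.0)
        assert p[f > 5.0].sum() < 0.01 * p.sum()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown noise kind"):
            synth_noise("pink", {}, 100, 500.0)


class TestAecgMixture:
    def test_degenerate_mixture_is_pure_maternal(self):
        cfg = SynthConfig(duration_s=10.0, fetal_amp_ratio=0.0, n_channels=1,
                          noise={"baseline_amp": 0, "powerline_amp": 0,
                                 "powerline_freq_hz": 50, "impulse_rate_per_s": 0,
                                 "impulse_amp": 0, "white_sd": 0}, seed=5)
        aecg, _ = synth_aecg(cfg)
        from fecgx.synthetic import synth_single_ecg
        maternal = synth_single_ecg(cfg.maternal_hr_bpm, cfg.duration_s, cfg.fs,
                                    DEFAULT_MORPHOLOGY, cfg.hr_jitter_sd,
                                    aecg.meta["maternal_seed"])
        np.testing.assert_allclose(
            aecg.samples[0], aecg.meta["channel_gains"][0] * maternal.samples[0])

    def test_mixture_is_exactly_linear(self, aecg_pair):
        # regenerate every component from the stored seeds; residual is the
        # fetal part, perfectly correlated with the clean fetal signal
        aecg, fecg = aecg_pair
        cfg = aecg.meta["config"]
        maternal = synth_single_ecg(cfg.maternal_hr_bpm, cfg.duration_s, cfg.fs,
                                    DEFAULT_MORPHOLOGY, cfg.hr_jitter_sd,
                                    aecg.meta["maternal_seed"])
        noise = np.zeros(aecg.n_samples)
        for kind, s in zip(("baseline", "powerline", "impulse", "white"),
                           aecg.meta["noise_seeds"][0]):
            noise += synth_noise(kind, cfg.noise, aecg.n_samples, cfg.fs, s)
        residual = (aecg.samples[0]
                    - aecg.meta["channel_gains"][0] * maternal.samples[0] - noise)
        rho = np.corrcoef(residual, fecg.samples[0])[0, 1]
        assert rho > 1 - 1e-9
        np.testing.assert_allclose(residual, cfg.fetal_amp_ratio * fecg.samples[0],
                                   atol=1e-9)

    def test_annotation_counts_match_rates(self):
        aecg, _ = synth_aecg(SynthConfig(duration_s=60.0, maternal_hr_bpm=80.0,
                                         fetal_hr_bpm=140.0, seed=9))
        assert abs(len(aecg.r_peaks["fetal"]) - 140) <= 3
        assert abs(len(aecg.r_peaks["maternal"]) - 80) <= 3

    def test_determinism(self):
        a1, f1 = synth_aecg(SynthConfig(duration_s=8.0, seed=77))
        a2, f2 = synth_aecg(SynthConfig(duration_s=8.0, seed=77))
        np.testing.assert_array_equal(a1.samples, a2.samples)
        np.testing.assert_array_equal(f1.samples, f2.samples)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(fetal_amp_ratio=1.5)
        with pytest.raises(ValueError):
            SynthConfig(maternal_hr_bpm=150.0, fetal_hr_bpm=140.0)
        with pytest.raises(ValueError):
            SynthConfig(noise={"powerline_freq_hz": 45})
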