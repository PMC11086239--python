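"""Synthetic abdominal/fetal ECG generation with ground-truth annotations.

The generator emulates the statistical structure a noninvasive fetal-ECG
extractor has to cope with: a strong maternal ECG, a weaker and faster fetal
ECG (amplitude ratio ~0.1-0.4), baseline wander below 5 Hz, powerline
interference at 50/60 Hz plus its 3rd harmonic, sparse impulse artifacts and
broadband noise.  Beats follow a sum-of-Gaussians PQRST template evaluated on
a phase variable that advances one full cycle per RR interval, with per-beat
Gaussian jitter of the instantaneous heart rate as a simple HRV proxy.

Everything is deterministic given the config seed, and every record carries
its fetal (and maternal) R-peak sample indices, so downstream detection can
be scored against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["SynthConfig", "EcgRecord", "synth_single_ecg", "synth_noise", "synth_aecg",
           "DEFAULT_MORPHOLOGY", "FETAL_MORPHOLOGY"]

# Per-wave (amplitude a [mV], width b [rad], phase theta [rad]) of the PQRST
# template z(phi) = sum_i a_i * exp(-wrap(phi - theta_i)^2 / (2 b_i^2)).
# Phases place P ~130 ms before R and T ~200 ms after R at a 0.8 s cycle.
DEFAULT_MORPHOLOGY: dict[str, tuple[float, float, float]] = {
    "P": (0.12, 0.22, -np.pi / 3),
    "Q": (-0.10, 0.06, -np.pi / 14),
    "R": (1.00, 0.09, 0.0),
    "S": (-0.20, 0.06, np.pi / 14),
    "T": (0.35, 0.40, np.pi / 2),
}

# Fetal QRS complexes are narrower than maternal ones; same template with
# tightened widths (amplitude scaling is applied by the mixture, not here).
FETAL_MORPHOLOGY: dict[str, tuple[float, float, float]] = {
    w: (a, b * 0.7, th) for w, (a, b, th) in DEFAULT_MORPHOLOGY.items()
}


@dataclass
class EcgRecord:
    """A multichannel sampled ECG with optional labelled R-peak annotations.

    samples: array [n_channels x n_samples], millivolt-scale arbitrary units.
    r_peaks: mapping from source label ("maternal", "fetal", "self") to sorted
        0-based sample indices.
    """

    samples: np.ndarray
    fs: float
    r_peaks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.samples.shape[1]
        for label, idx in list(self.r_peaks.items()):
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(
                    f"annotation '{label}' has indices outside [0, {n})")
            self.r_peaks[label] = idx

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SynthConfig:
    """Study conditions for the synthetic AECG mixture."""

    duration_s: float = 60.0
    fs: float = 500.0
    maternal_hr_bpm: float = 75.0
    fetal_hr_bpm: float = 140.0
    fetal_amp_ratio: float = 0.25
    n_channels: int = 4
    noise: dict = field(default_factory=lambda: {
        "baseline_amp": 0.3,        # mV, <5 Hz wander
        "powerline_amp": 0.2,       # mV at the mains fundamental
        "powerline_freq_hz": 50.0,
        "impulse_rate_per_s": 0.5,  # Poisson arrivals
        "impulse_amp": 3.0,         # mV spike height (electrode-pop scale)
        "white_sd": 0.05,           # mV broadband noise
    })
    hr_jitter_sd: float = 2.0       # beats/min, per-beat
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if not (0.0 <= self.fetal_amp_ratio <= 1.0):
            raise ValueError("fetal_amp_ratio must be in [0, 1]")
        if self.noise.get("powerline_freq_hz", 50.0) not in (50.0, 60.0, 50, 60):
            raise ValueError("powerline_freq_hz must be 50 or 60")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.fetal_hr_bpm <= self.maternal_hr_bpm:
            raise ValueError("fetal heart rate must exceed the maternal rate")


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    return np.mod(phi + np.pi, 2.0 * np.pi) - np.pi


def _template(phi: np.ndarray, morph: Mapping[str, tuple[float, float, float]]) -> np.ndarray:
    z = np.zeros_like(phi)
    for a, b, theta in morph.values():
        d = _wrap_phase(phi - theta)
        z += a * np.exp(-d * d / (2.0 * b * b))
    return z


def synth_single_ecg(hr_bpm: float, duration_s: float, fs: float,
                     morph_params: Mapping[str, tuple[float, float, float]] | None = None,
                     hr_jitter_sd: float = 0.0, seed: int = 0) -> EcgRecord:
    """Generate one ECG channel from the sum-of-Gaussians beat model.

    The beat phase advances linearly from one R-peak to the next; per-beat
    instantaneous rate is hr_bpm plus Gaussian jitter (sd ``hr_jitter_sd``).
    R-peak annotations are stored under label ``"self"``.
    """
    if fs <= 0 or duration_s <= 0:
        raise ValueError("fs and duration_s must be positive")
    if not (30.0 <= hr_bpm <= 300.0):
        raise ValueError("hr_bpm must lie in [30, 300] beats/min")
    morph = DEFAULT_MORPHOLOGY if morph_params is None else dict(morph_params)
    if not morph:
        raise ValueError("morph_params must define at least one wave")

    rng = np.random.default_rng(seed)
    # Beat-by-beat R times; first R placed half an RR interval into the record.
    r_times = []
    rr0 = 60.0 / hr_bpm
    t = 0.5 * rr0
    while t < duration_s + rr0:  # one spare beat past the end for phase interp
        r_times.append(t)
        hr = hr_bpm + (rng.normal(0.0, hr_jitter_sd) if hr_jitter_sd > 0 else 0.0)
        hr = float(np.clip(hr, 30.0, 300.0))
        t += 60.0 / hr
    r_times = np.asarray(r_times)

    n = int(round(duration_s * fs))
    ts = np.arange(n) / fs
    # Phase: 0 at each R-peak, advancing 2*pi per RR interval.
    knots = np.concatenate(([r_times[0] - rr0], r_times))
    cycle = np.arange(len(knots), dtype=np.float64)
    phi = np.interp(ts, knots, cycle, left=np.nan, right=np.nan)
    # Before the first knot / after the last: extend linearly with edge RR.
    head = ts < knots[0]
    phi[head] = (ts[head] - knots[0]) / (knots[1] - knots[0])
    tail = ts > knots[-1]
    phi[tail] = cycle[-1] + (ts[tail] - knots[-1]) / (knots[-1] - knots[-2])
    signal = _template(2.0 * np.pi * phi, morph)

    peaks = np.round(r_times[r_times < duration_s] * fs).astype(np.int64)
    peaks = peaks[peaks < n]
    return EcgRecord(signal[None, :], fs, {"self": peaks},
                     meta={"hr_bpm": hr_bpm, "hr_jitter_sd": hr_jitter_sd, "seed": seed})


def synth_noise(kind: str, params: Mapping[str, float], n_samples: int,
                fs: float, seed: int = 0) -> np.ndarray:
    """Generate one noise component of the abdominal mixture.

    kinds: ``baseline`` (sub-5 Hz sinusoidal wander), ``powerline``
    (mains fundamental + 3rd harmonic), ``impulse`` (sparse Poisson spikes),
    ``white`` (Gaussian).
    """
    rng = np.random.default_rng(seed)
    ts = np.arange(n_samples) / fs
    if kind == "baseline":
        amp = float(params.get("baseline_amp", params.get("amp", 0.0)))
        out = np.zeros(n_samples)
        # three incommensurate slow sinusoids, all well below 5 Hz
        for f in (0.08, 0.21, 0.37):
            f_jit = f * (1.0 + 0.2 * rng.uniform(-1, 1))
            out += np.sin(2.0 * np.pi * f_jit * ts + rng.uniform(0, 2 * np.pi))
        return amp * out / 3.0
    if kind == "powerline":
        amp = float(params.get("powerline_amp", params.get("amp", 0.0)))
        f0 = float(params.get("powerline_freq_hz", 50.0))
        phase = rng.uniform(0, 2 * np.pi)
        return amp * (np.sin(2 * np.pi * f0 * ts + phase)
                      + 0.3 * np.sin(2 * np.pi * 3 * f0 * ts + 3 * phase))
    if kind == "impulse":
        rate = float(params.get("impulse_rate_per_s", params.get("rate", 0.0)))
        amp = float(params.get("impulse_amp", params.get("amp", 0.0)))
        out = np.zeros(n_samples)
        n_spikes = rng.poisson(rate * n_samples / fs)
        pos = rng.integers(0, max(n_samples - 3, 1), size=n_spikes)
        for p in pos:
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            height = amp * (0.7 + 0.6 * rng.uniform())
            out[p] += sign * height            # dominant single-sample spike
            out[p + 1] += sign * height * 0.3  # short decay flank
            out[p + 2] += sign * height * 0.1
        return out
    if kind == "white":
        sd = float(params.get("white_sd", params.get("sd", 0.0)))
        return sd * rng.standard_normal(n_samples)
    raise ValueError(f"unknown noise kind: {kind!r}")


def synth_aecg(config: SynthConfig) -> tuple[EcgRecord, EcgRecord]:
    """Generate a (noisy multichannel AECG, clean single-channel FECG) pair.

    Each abdominal channel is ``gain_ch * maternal + fetal_amp_ratio * fetal
    + noise_ch`` with an independent noise realization per channel; the clean
    fetal record is the noise-free fetal signal at unit template amplitude.
    AECG annotations carry both maternal and fetal ground truth.
    """
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8 + 4 * config.n_channels)

    maternal = synth_single_ecg(config.maternal_hr_bpm, config.duration_s, config.fs,
                                DEFAULT_MORPHOLOGY, config.hr_jitter_sd, int(seeds[0]))
    fetal = synth_single_ecg(config.fetal_hr_bpm, config.duration_s, config.fs,
                             FETAL_MORPHOLOGY, config.hr_jitter_sd, int(seeds[1]))
    n = maternal.n_samples
    channels = np.zeros((config.n_channels, n))
    gains = 1.0 + 0.2 * np.random.default_rng(int(seeds[2])).uniform(-1, 1, config.n_channels)
    for ch in range(config.n_channels):
        noise = np.zeros(n)
        base = 8 + 4 * ch
        for k, kind in enumerate(("baseline", "powerline", "impulse", "white")):
            noise += synth_noise(kind, config.noise, n, config.fs, int(seeds[base + k]))
        channels[ch] = gains[ch] * maternal.samples[0] \
            + config.fetal_amp_ratio * fetal.samples[0] + noise

    noise_seeds = [[int(seeds[8 + 4 * ch + k]) for k in range(4)]
                   for ch in range(config.n_channels)]
    aecg = EcgRecord(channels, config.fs,
                     {"maternal": maternal.r_peaks["self"],
                      "fetal": fetal.r_peaks["self"]},
                     meta={"config": config, "channel_gains": gains,
                           # component seeds let callers regenerate the exact
                           # mixture terms (mixture-linearity diagnostics)
                           "maternal_seed": int(seeds[0]),
                           "fetal_seed": int(seeds[1]),
                           "noise_seeds": noise_seeds})
    fecg_clean = EcgRecord(fetal.samples.copy(), config.fs,
                           {"fetal": fetal.r_peaks["self"].copy()},
                           meta={"config": config})
    return aecg, fecg_clean
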