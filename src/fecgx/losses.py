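"""CycleGAN objectives: cycle, adversarial, spectral identity, total.

All losses are built from autodiff tensors so they can drive training, but
accept plain numpy batches.  Conventions:

* cycle loss: mean absolute reconstruction error per element, summed over the
  two directions G2(G1(x)) vs x and G1(G2(y)) vs y;
* adversarial loss: per-patch log scores averaged over patches and batch;
  the discriminator minimizes the negation of the quantity it maximizes, the
  generator uses the non-saturating -E[log D(fake)] form;
* identity loss, three summands per batch of size N:
      (2/N) sum_i [1 - rho(P(y_i), P(G(x_i)))] * rho(P(y_i), P(x_i))
    + (4/N) sum_i [1 - rho(y_i, G(x_i))]
    + (1/N) sum_i |p(x_i) - p(G(x_i))| / p(x_i)
  with P a Welch power spectral density, rho the population Pearson
  correlation and p the mean squared amplitude.  The first summand's
  ambiguous grouping is implemented as the bounded product form; a quotient
  form is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .autodiff import Tensor, tensor

__all__ = ["LossWeights", "LossReport", "welch_psd", "pearson",
           "cycle_loss", "adversarial_loss", "identity_loss", "total_loss"]

_EPS = 1e-7  # probability clamp for the adversarial logs


@dataclass
class LossWeights:
    """lambda (cycle weight, aliased alpha) and beta (identity weight)."""

    lambda_cycle: float = 10.0
    beta: float = 5.0

    def __post_init__(self) -> None:
        if self.lambda_cycle < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")

    @property
    def alpha(self) -> float:
        return self.lambda_cycle


@dataclass
class LossReport:
    l_cycle: float
    l_gan_fwd: float
    l_gan_bwd: float
    l_identity_g1: float
    l_identity_g2: float
    l_total: float = 0.0
    identity_breakdown_g1: dict = field(default_factory=dict)
    identity_breakdown_g2: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# differentiable Welch PSD and Pearson correlation
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _dft_matrices(nperseg: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = np.arange(nperseg)
    k = np.arange(nperseg // 2 + 1)
    ang = 2.0 * np.pi * np.outer(n, k) / nperseg
    window = np.hanning(nperseg + 1)[:-1]  # periodic Hann, as Welch uses
    onesided = np.full(nperseg // 2 + 1, 2.0)
    onesided[0] = 1.0
    if nperseg % 2 == 0:
        onesided[-1] = 1.0
    return np.cos(ang), -np.sin(ang), window, onesided


def welch_psd(x, nperseg: int = 256, overlap: float = 0.5) -> Tensor:
    """Welch averaged periodogram, unnormalized, differentiable.

    x: (B, L) tensor or array.  Hann window, mean detrend per frame, 50%
    overlap by default; the absolute scale is irrelevant for the correlation
    terms that consume it (matches scipy.signal.welch up to a constant).
    """
    t = x if isinstance(x, Tensor) else tensor(np.asarray(x, dtype=np.float64))
    if t.ndim == 1:
        t = t.reshape((1, -1))
    B, L = t.shape
    nperseg = min(nperseg, L)
    step = max(1, int(nperseg * (1.0 - overlap)))
    cos_m, sin_m, window, onesided = _dft_matrices(nperseg)
    acc = None
    n_frames = (L - nperseg) // step + 1
    for j in range(n_frames):
        frame = t[:, j * step:j * step + nperseg]
        frame = (frame - frame.mean(axis=1, keepdims=True)) * window
        re = frame @ cos_m
        im = frame @ sin_m
        p = (re * re + im * im) * onesided
        acc = p if acc is None else acc + p
    return acc * (1.0 / n_frames)


def _rowwise_pearson(a: Tensor, b: Tensor) -> Tensor:
    """Population Pearson correlation per row of two (B, K) tensors."""
    for name, t in (("first", a), ("second", b)):
        sd = t.data.std(axis=1)
        if (sd <= 0).any():
            i = int(np.argmax(sd <= 0))
            raise ValueError(f"zero-variance {name} argument in row {i}: "
                             "Pearson correlation undefined")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    cov = (ac * bc).mean(axis=1)
    return cov / ((ac * ac).mean(axis=1).sqrt() * (bc * bc).mean(axis=1).sqrt())


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Population Pearson correlation of two 1-D signals."""
    r = _rowwise_pearson(tensor(np.asarray(x, dtype=np.float64).reshape(1, -1)),
                         tensor(np.asarray(y, dtype=np.float64).reshape(1, -1)))
    return float(r.data[0])


def _as_batch(x) -> Tensor:
    t = x if isinstance(x, Tensor) else tensor(np.asarray(x, dtype=np.float64))
    return t.reshape((1, -1)) if t.ndim == 1 else t


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def cycle_loss(G1, G2, x_batch, y_batch) -> Tensor:
    """Mean L1 reconstruction error over both cycle directions."""
    x = _as_batch(x_batch)
    y = _as_batch(y_batch)
    fwd = (G2(G1(x)) - x).abs().mean()
    bwd = (G1(G2(y)) - y).abs().mean()
    return fwd + bwd


def _clamped_probs(p: Tensor) -> Tensor:
    if (p.data <= 0).any() or (p.data >= 1).any():
        p = p.clip(_EPS, 1.0 - _EPS)
    return p


def adversarial_loss(D, real_batch, fake_batch) -> tuple[Tensor, Tensor]:
    """(d_loss, g_loss) for one GAN direction.

    d_loss = -(E[log D(real)] + E[log(1 - D(fake))]) averaged over patches;
    g_loss = -E[log D(fake)] (non-saturating).  Pass a detached fake batch
    when optimizing the discriminator.
    """
    real = _as_batch(real_batch)
    fake = _as_batch(fake_batch)
    if len(real.data) == 0 or len(fake.data) == 0:
        raise ValueError("empty batch")
    d_real = _clamped_probs(D(real))
    d_fake = _clamped_probs(D(fake))
    d_loss = -(d_real.log().mean() + (1.0 - d_fake).log().mean())
    g_loss = -(d_fake.log().mean())
    return d_loss, g_loss


def _identity_terms(g_out: Tensor, x: Tensor, y: Tensor, psd_fn,
                    form: str) -> tuple[Tensor, dict]:
    n = x.shape[0]
    if g_out.shape != x.shape or y.shape[1] != x.shape[1]:
        raise ValueError("identity loss requires equal-length segments")
    power_check = (x.data ** 2).mean(axis=1)
    if (power_check <= 0).any():
        i = int(np.argmax(power_check <= 0))
        raise ValueError(f"zero-power input segment {i}: identity power term undefined")
    p_x = psd_fn(x)
    p_y = psd_fn(y)
    p_g = psd_fn(g_out)
    rho_spec_gen = _rowwise_pearson(p_y, p_g)
    rho_spec_in = _rowwise_pearson(p_y, p_x)
    if form == "product":
        term1 = ((1.0 - rho_spec_gen) * rho_spec_in).sum() * (2.0 / n)
    elif form == "quotient":
        term1 = ((1.0 - rho_spec_gen) / rho_spec_in).sum() * (2.0 / n)
    else:
        raise ValueError(f"unknown identity form {form!r}")
    term2 = (1.0 - _rowwise_pearson(y, g_out)).sum() * (4.0 / n)
    power_x = (x * x).mean(axis=1)
    if (power_x.data <= 0).any():
        i = int(np.argmax(power_x.data <= 0))
        raise ValueError(f"zero-power input segment {i}: identity power term undefined")
    power_g = (g_out * g_out).mean(axis=1)
    term3 = ((power_x - power_g).abs() / power_x).sum() * (1.0 / n)
    total = term1 + term2 + term3
    breakdown = {"spectral": term1.item(), "correlation": term2.item(),
                 "power": term3.item()}
    return total, breakdown


def identity_loss(G, x_batch, y_batch, psd_fn=welch_psd,
                  form: str = "product") -> tuple[Tensor, dict]:
    """Distortion penalty tying G(x) to the target domain y.

    Returns (total, breakdown) with the three summands reported separately.
    """
    x = _as_batch(x_batch)
    y = _as_batch(y_batch)
    return _identity_terms(G(x), x, y, psd_fn, form)


def total_loss(report: LossReport, weights: LossWeights) -> float:
    """Weighted generator objective: adversarial + lambda*cycle + beta*identity."""
    if weights.lambda_cycle < 0 or weights.beta < 0:
        raise ValueError("loss weights must be non-negative")
    return (report.l_gan_fwd + report.l_gan_bwd
            + weights.lambda_cycle * report.l_cycle
            + weights.beta * (report.l_identity_g1 + report.l_identity_g2))
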