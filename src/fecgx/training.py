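"""Alternating adversarial optimization of the two GAN pairs, and extraction.

Each step updates the two discriminators on real/generated batches first
(minimizing the negation of the quantity they maximize), then the two
generators on the weighted total: non-saturating adversarial terms +
lambda * cycle loss + beta * (identity(G1) + identity(G2)).  AECG-side and
FECG-side batches are drawn independently by default (unpaired translation);
a paired mode that keeps batch items aligned is available for synthetic
diagnostics where the identity correlation terms are meaningful sample-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, no_grad, tensor
from .io_segment import SEGMENT_LEN, SEGMENT_OVERLAP, SegmentSet, reassemble, segment
from .losses import LossWeights, _clamped_probs, _identity_terms, welch_psd
from .model import Discriminator, Generator, save_checkpoint
from .preprocess import PreprocessConfig, preprocess_pipeline
from .synthetic import EcgRecord

__all__ = ["TrainConfig", "ModelPair", "TrainingDivergedError", "train", "extract"]


class TrainingDivergedError(RuntimeError):
    """Raised when a loss goes non-finite; models hold the last-good state."""


@dataclass
class ModelPair:
    g1: Generator       # AECG -> FECG
    g2: Generator       # FECG -> AECG
    dx: Discriminator   # judges the AECG domain
    dy: Discriminator   # judges the FECG domain

    def as_dict(self) -> dict:
        return {"g1": self.g1, "g2": self.g2, "dx": self.dx, "dy": self.dy}


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 80
    batch_size: int = 32
    seed: int = 0
    device: str = "cpu"
    checkpoint_every: int = 10
    weights: LossWeights = field(default_factory=LossWeights)
    paired: bool = False
    identity_form: str = "product"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("need at least one epoch")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")


def _snapshot(models: ModelPair) -> dict[str, list[np.ndarray]]:
    return {k: [a.copy() for a in m.state_arrays()]
            for k, m in models.as_dict().items()}


def _restore(models: ModelPair, snap: dict[str, list[np.ndarray]]) -> None:
    for k, m in models.as_dict().items():
        m.load_state_arrays(snap[k])


def train(models: ModelPair, x_segments: SegmentSet | np.ndarray,
          y_segments: SegmentSet | np.ndarray, config: TrainConfig,
          out_dir: str | Path | None = None) -> list[dict]:
    """Train the CycleGAN pair; returns per-epoch loss history rows.

    x_segments: AECG-domain windows; y_segments: FECG-domain windows.  The
    domains need not be paired (``config.paired`` aligns them when they are).
    History rows carry every loss component; ``l_total`` is recomputed from
    the logged component means with the configured weights, exactly.
    """
    x = x_segments.segments if isinstance(x_segments, SegmentSet) else np.asarray(x_segments)
    y = y_segments.segments if isinstance(y_segments, SegmentSet) else np.asarray(y_segments)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both training domains must be nonempty")
    if config.paired and len(x) != len(y):
        raise ValueError("paired mode requires equally sized domains")
    rng = np.random.default_rng(config.seed)
    w = config.weights
    opt_g = Adam(models.g1.parameters() + models.g2.parameters(),
                 lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    opt_d = Adam(models.dx.parameters() + models.dy.parameters(),
                 lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    n_steps = max(1, min(len(x), len(y)) // config.batch_size)
    history: list[dict] = []
    last_good = _snapshot(models)
    out_dir = Path(out_dir) if out_dir is not None else None

    for epoch in range(1, config.epochs + 1):
        perm_x = rng.permutation(len(x))
        perm_y = perm_x if config.paired else rng.permutation(len(y))
        sums = {k: 0.0 for k in ("l_cycle", "l_gan_fwd", "l_gan_bwd",
                                 "l_identity_g1", "l_identity_g2", "l_d")}
        for s in range(n_steps):
            sl = slice(s * config.batch_size, (s + 1) * config.batch_size)
            xb = x[perm_x[sl]]
            yb = y[perm_y[sl]]

            models.g1.train_mode(True)
            models.g2.train_mode(True)
            fy = models.g1(xb)          # G1(x): estimated FECG
            fx = models.g2(yb)          # G2(y): estimated AECG

            # --- discriminators: maximize the GAN quantities -------------
            d_loss = (-(_clamped_probs(models.dy(yb)).log().mean()
                        + (1.0 - _clamped_probs(models.dy(fy.detach()))).log().mean())
                      - (_clamped_probs(models.dx(xb)).log().mean()
                         + (1.0 - _clamped_probs(models.dx(fx.detach()))).log().mean()))
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # --- generators: weighted total ------------------------------
            xt, yt = tensor(xb), tensor(yb)
            cyc = (models.g2(fy) - xt).abs().mean() + (models.g1(fx) - yt).abs().mean()
            g_fwd = -(_clamped_probs(models.dy(fy)).log().mean())
            g_bwd = -(_clamped_probs(models.dx(fx)).log().mean())
            id1, _ = _identity_terms(fy, xt, yt, welch_psd, config.identity_form)
            id2, _ = _identity_terms(fx, yt, xt, welch_psd, config.identity_form)
            g_total = g_fwd + g_bwd + w.lambda_cycle * cyc + w.beta * (id1 + id2)

            vals = {"l_cycle": cyc.item(), "l_gan_fwd": g_fwd.item(),
                    "l_gan_bwd": g_bwd.item(), "l_identity_g1": id1.item(),
                    "l_identity_g2": id2.item(), "l_d": d_loss.item()}
            if not all(np.isfinite(v) for v in vals.values()):
                _restore(models, last_good)
                if out_dir is not None:
                    save_checkpoint(out_dir / "last_good.npz", models.as_dict(),
                                    {"epoch": epoch - 1})
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} step {s}; "
                    "models restored to the last-good checkpoint")

            opt_g.zero_grad()
            g_total.backward()
            opt_g.step()
            for k, v in vals.items():
                sums[k] += v

        row = {k: v / n_steps for k, v in sums.items()}
        row["epoch"] = epoch
        # exact bookkeeping: total recomputed from the logged means
        row["l_total"] = (row["l_gan_fwd"] + row["l_gan_bwd"]
                          + w.lambda_cycle * row["l_cycle"]
                          + w.beta * (row["l_identity_g1"] + row["l_identity_g2"]))
        history.append(row)
        last_good = _snapshot(models)
        if out_dir is not None and (epoch % config.checkpoint_every == 0
                                    or epoch == config.epochs):
            save_checkpoint(out_dir / f"epoch_{epoch:04d}.npz", models.as_dict(),
                            {"epoch": epoch, "history": history})
    return history


def extract(g1: Generator, record: EcgRecord,
            preprocess_cfg: PreprocessConfig | None = None, channel: int = 0,
            n: int = SEGMENT_LEN, overlap: int = SEGMENT_OVERLAP,
            model_fs: float = 500.0, resample: bool = False,
            batch: int = 64) -> EcgRecord:
    """Run the trained G1 over a record: preprocess, segment, overlap-average.

    The returned record holds the estimated FECG for one channel, trimmed to
    the region the segmentation covers; annotations are carried over (indices
    within the covered region only).
    """
    if record.fs != model_fs:
        if not resample:
            raise ValueError(f"record fs {record.fs} != model fs {model_fs}; "
                             "pass resample=True to convert")
        from .io_segment import fft_resample
        record = fft_resample(record, model_fs)
    if preprocess_cfg is not None:
        record, _ = preprocess_pipeline(record, preprocess_cfg)
    segset = segment(record, n, overlap, channels=[channel], role="extract")
    g1.train_mode(False)
    outs = []
    with no_grad():
        for i in range(0, len(segset), batch):
            outs.append(g1(segset.segments[i:i + batch]).data)
    est_set = SegmentSet(np.concatenate(outs), record.fs, segset.origin, "extract")
    est = reassemble(est_set, channel=channel)
    peaks = {label: idx[idx < len(est)].copy()
             for label, idx in record.r_peaks.items()}
    meta = dict(record.meta)
    meta["extracted_channel"] = channel
    return EcgRecord(est[None, :], record.fs, peaks, meta)
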