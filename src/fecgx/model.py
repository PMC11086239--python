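"""CNN-BiLSTM generators and 1-D PatchGAN discriminators.

The generator maps a 1024-sample abdominal segment to an equal-length fetal
estimate: three parallel 1-D convolution branches (multi-scale kernels,
channel schedule doubling from the base width, max-pooling per block) feed a
dropout + per-step fully connected resize, a stacked bidirectional LSTM, three
parallel output heads (summed), and a final fully connected resize back to the
input length.

The discriminator halves the temporal size with stride-2 kernel-2
convolutions (LeakyReLU 0.2, channels doubling from 64), pools to 16 temporal
positions, and scores each with a final stride-1 convolution + sigmoid: a 4x4
grid of per-patch authenticity probabilities.  A non-patch ("basic") variant
with a single global score is available for ablations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
import json

import numpy as np

from .autodiff import (Tensor, avgpool_to, concat, conv1d, get_default_dtype,
                       maxpool1d, no_grad, tensor)

__all__ = ["GeneratorConfig", "DiscriminatorConfig", "PatchScores",
           "Generator", "Discriminator", "build_generator", "build_discriminator",
           "save_checkpoint", "load_checkpoint"]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    n_conv_branches: int = 3
    n_conv_layers: int = 3            # conv blocks per branch
    base_channels: int = 64           # doubles per block: 64 -> 128 -> 256
    conv_kernel_sizes: tuple[int, ...] = (3, 5, 7)  # one width per branch
    pool_size: int | tuple[int, ...] = 2  # scalar or one pool factor per block
    dropout_rate: float = 0.5
    bilstm_hidden: int = 128
    bilstm_layers: int = 2
    n_output_heads: int = 3           # P-wave / QRS / ST feature heads
    segment_len: int = 1024
    in_channels: int = 1              # abdominal leads consumed per forward pass
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conv_branches < 1 or self.n_conv_layers < 1:
            raise ValueError("need at least one branch and one conv block")
        if len(self.conv_kernel_sizes) < self.n_conv_branches:
            raise ValueError("one kernel width per branch required")
        total = int(np.prod(self.pool_sizes))
        if self.segment_len % total:
            raise ValueError(
                f"segment_len {self.segment_len} not divisible by the pooling "
                f"product {total}; cannot produce an equal-length output")

    @property
    def pool_sizes(self) -> tuple[int, ...]:
        if isinstance(self.pool_size, (tuple, list)):
            if len(self.pool_size) != self.n_conv_layers:
                raise ValueError("one pool factor per conv block required")
            return tuple(int(p) for p in self.pool_size)
        return (int(self.pool_size),) * self.n_conv_layers

    @property
    def branch_channels(self) -> list[int]:
        return [self.base_channels * 2 ** j for j in range(self.n_conv_layers)]

    @property
    def seq_len(self) -> int:
        return self.segment_len // int(np.prod(self.pool_sizes))


@dataclass
class DiscriminatorConfig:
    n_layers: int = 4                 # stride-2 convs; a stride-1 scorer follows
    base_channels: int = 64           # doubles per layer
    kernel_size: int = 2
    leaky_slope: float = 0.2
    patch: bool = True                # False -> single global score ("basic")
    segment_len: int = 1024
    seed: int = 0
    N_PATCHES = 16                    # 4 x 4 grid

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        positions = self.segment_len // 2 ** self.n_layers
        if self.patch and (positions < self.N_PATCHES
                           or positions % self.N_PATCHES):
            raise ValueError(
                f"{self.n_layers} stride-2 layers leave {positions} temporal "
                f"positions; cannot form a 4x4 patch grid")


@dataclass
class PatchScores:
    """4x4 grid of per-patch authenticity probabilities."""

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64).reshape(4, 4)

    @property
    def mean_score(self) -> float:
        return float(self.X.mean())


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.astype(get_default_dtype()).copy()


def _param(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    t = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape))
    t.requires_grad = True
    return t


def _zeros(shape) -> Tensor:
    t = Tensor(np.zeros(shape))
    t.requires_grad = True
    return t


class Conv1d(Module):
    def __init__(self, rng, c_in: int, c_out: int, k: int,
                 stride: int = 1, padding: int = 0):
        self.w = _param(rng, (c_out, c_in, k), c_in * k)
        self.b = _zeros(c_out)
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride, padding=self.padding)

    def parameters(self):
        return [self.w, self.b]


class Dense(Module):
    """Affine map over the last axis (leading axes are batch-like)."""

    def __init__(self, rng, d_in: int, d_out: int):
        self.w = _param(rng, (d_in, d_out), d_in)
        self.b = _zeros(d_out)
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        flat = x.reshape((-1, self.d_in)) if x.ndim != 2 else x
        out = flat @ self.w + self.b
        return out.reshape(lead + (self.d_out,)) if x.ndim != 2 else out

    def parameters(self):
        return [self.w, self.b]


class LSTM(Module):
    """Single-direction LSTM over (B, T, I) -> (B, T, H)."""

    def __init__(self, rng, d_in: int, hidden: int):
        self.h = hidden
        self.wx = _param(rng, (d_in, 4 * hidden), d_in)
        self.wh = _param(rng, (hidden, 4 * hidden), hidden)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b)
        self.b.requires_grad = True

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.h
        # input projection for all timesteps at once
        xf = (x.reshape((B * T, -1)) @ self.wx + self.b).reshape((B, T, 4 * H))
        h = tensor(np.zeros((B, H)))
        c = tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            z = xf[:, t, :] + h @ self.wh
            i = z[:, :H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h.reshape((B, 1, H)))
        return concat(outs, axis=1)

    def parameters(self):
        return [self.wx, self.wh, self.b]


class BiLSTM(Module):
    def __init__(self, rng, d_in: int, hidden: int):
        self.fwd = LSTM(rng, d_in, hidden)
        self.bwd = LSTM(rng, d_in, hidden)

    def __call__(self, x: Tensor) -> Tensor:
        rev = x[:, ::-1, :]
        out_b = self.bwd(rev)[:, ::-1, :]
        return concat([self.fwd(x), out_b], axis=2)

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class Generator(Module):
    """G: segment[N] -> segment[N] (AECG -> FECG or the reverse)."""

    def __init__(self, config: GeneratorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.default_rng(config.seed + 1).integers(2**31))
        self.training = True
        cfg = config
        self.branches: list[list[Conv1d]] = []
        for b in range(cfg.n_conv_branches):
            k = cfg.conv_kernel_sizes[b]
            layers, c_in = [], cfg.in_channels
            for c_out in cfg.branch_channels:
                layers.append(Conv1d(rng, c_in, c_out, k, padding=(k - 1) // 2))
                c_in = c_out
            self.branches.append(layers)
        feat = cfg.branch_channels[-1] * cfg.n_conv_branches
        self.resize_in = Dense(rng, feat, cfg.bilstm_hidden)
        self.lstms: list[BiLSTM] = []
        d = cfg.bilstm_hidden
        for _ in range(cfg.bilstm_layers):
            self.lstms.append(BiLSTM(rng, d, cfg.bilstm_hidden))
            d = 2 * cfg.bilstm_hidden
        self.heads = [Dense(rng, d, d) for _ in range(cfg.n_output_heads)]
        self.out = Dense(rng, d, cfg.segment_len // cfg.seq_len)

    def parameters(self):
        ps = [p for br in self.branches for layer in br for p in layer.parameters()]
        ps += self.resize_in.parameters()
        for l in self.lstms:
            ps += l.parameters()
        for h in self.heads:
            ps += h.parameters()
        ps += self.out.parameters()
        return ps

    def train_mode(self, on: bool = True) -> None:
        self.training = on

    def __call__(self, x) -> Tensor:
        cfg = self.config
        t = x if isinstance(x, Tensor) else tensor(np.asarray(x, dtype=np.float64))
        if t.ndim == 1:
            t = t.reshape((1, -1))
        if t.ndim == 2:
            t = t.reshape((t.shape[0], 1, t.shape[1]))
        B, C, N = t.shape
        if N != cfg.segment_len:
            raise ValueError(f"expected segments of length {cfg.segment_len}, got {N}")
        if C != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} input channel(s), got {C}")
        z = t
        feats = []
        pools = cfg.pool_sizes
        for layers in self.branches:
            h = z
            for conv, p in zip(layers, pools):
                h = maxpool1d(conv(h).relu(), p)
            feats.append(h)
        h = concat(feats, axis=1)                       # (B, F, T)
        if self.training and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            mask = self._dropout_rng.uniform(size=h.shape) < keep
            h = h * (mask / keep)
        h = h.transpose((0, 2, 1))                      # (B, T, F)
        h = self.resize_in(h).relu()
        for l in self.lstms:
            h = l(h)
        s = self.heads[0](h)
        for head in self.heads[1:]:
            s = s + head(h)
        y = self.out(s)                                 # (B, T, N/T)
        return y.reshape((B, N))

    def summary(self) -> str:
        cfg = self.config
        lines = [f"Generator(N={cfg.segment_len})"]
        for b in range(cfg.n_conv_branches):
            lines.append(f"  branch {b}: k={cfg.conv_kernel_sizes[b]} "
                         f"channels {cfg.branch_channels} pool {cfg.pool_size}")
        lines.append(f"  dropout p={cfg.dropout_rate}; resize -> {cfg.bilstm_hidden}")
        lines.append(f"  BiLSTM x{cfg.bilstm_layers} hidden {cfg.bilstm_hidden}; "
                     f"{cfg.n_output_heads} output heads")
        lines.append(f"  output resize {2 * cfg.bilstm_hidden} -> "
                     f"{cfg.segment_len // cfg.seq_len} per step")
        lines.append(f"  parameters: {self.n_params}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# discriminator
# ---------------------------------------------------------------------------

class Discriminator(Module):
    """D: segment[N] -> 16 patch probabilities (or one global score)."""

    def __init__(self, config: DiscriminatorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cfg = config
        self.convs: list[Conv1d] = []
        c_in = 1
        for j in range(cfg.n_layers):
            c_out = min(cfg.base_channels * 2 ** j, 8 * cfg.base_channels)
            self.convs.append(Conv1d(rng, c_in, c_out, cfg.kernel_size, stride=2))
            c_in = c_out
        if cfg.patch:
            self.score = Conv1d(rng, c_in, 1, 1, stride=1)  # stride-1 scorer
        else:
            self.score = Dense(rng, c_in, 1)

    def parameters(self):
        return [p for c in self.convs for p in c.parameters()] + self.score.parameters()

    def __call__(self, x) -> Tensor:
        cfg = self.config
        t = x if isinstance(x, Tensor) else tensor(np.asarray(x, dtype=np.float64))
        if t.ndim == 1:
            t = t.reshape((1, -1))
        B, N = t.shape
        h = t.reshape((B, 1, N))
        for conv in self.convs:
            h = conv(h).leaky_relu(cfg.leaky_slope)
        if cfg.patch:
            h = avgpool_to(h, cfg.N_PATCHES)
            return self.score(h).sigmoid().reshape((B, cfg.N_PATCHES))
        h = h.mean(axis=2)                              # global average pool
        return self.score(h).sigmoid()                  # (B, 1)

    def patch_scores(self, segment: np.ndarray) -> PatchScores:
        if not self.config.patch:
            raise ValueError("basic discriminator has no patch grid")
        with no_grad():
            probs = self(np.asarray(segment, dtype=np.float64).reshape(1, -1))
        return PatchScores(probs.data[0])


def build_generator(config: GeneratorConfig | None = None) -> Generator:
    return Generator(config or GeneratorConfig())


def build_discriminator(config: DiscriminatorConfig | None = None) -> Discriminator:
    return Discriminator(config or DiscriminatorConfig())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, models: dict[str, Module],
                    extra: dict | None = None) -> None:
    """Save model parameters (npz) with their configs embedded as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {"extra": extra or {}}
    for name, model in models.items():
        cfg = asdict(model.config)
        cfg["__class__"] = type(model.config).__name__
        meta[name] = cfg
        for i, a in enumerate(model.state_arrays()):
            arrays[f"{name}__{i}"] = a
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, default=float).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict[str, Module], dict]:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"].tobytes()).decode())
        models: dict[str, Module] = {}
        for name, cfg in meta.items():
            if name == "extra":
                continue
            cls = cfg.pop("__class__")
            if cls == "GeneratorConfig":
                model: Module = Generator(GeneratorConfig(
                    n_conv_branches=int(cfg["n_conv_branches"]),
                    n_conv_layers=int(cfg["n_conv_layers"]),
                    base_channels=int(cfg["base_channels"]),
                    conv_kernel_sizes=tuple(int(v) for v in cfg["conv_kernel_sizes"]),
                    pool_size=(tuple(int(v) for v in cfg["pool_size"])
                               if isinstance(cfg["pool_size"], (list, tuple))
                               else int(cfg["pool_size"])),
                    dropout_rate=float(cfg["dropout_rate"]),
                    bilstm_hidden=int(cfg["bilstm_hidden"]),
                    bilstm_layers=int(cfg["bilstm_layers"]),
                    n_output_heads=int(cfg["n_output_heads"]),
                    segment_len=int(cfg["segment_len"]),
                    in_channels=int(cfg.get("in_channels", 1)),
                    seed=int(cfg["seed"])))
            else:
                model = Discriminator(DiscriminatorConfig(
                    n_layers=int(cfg["n_layers"]), base_channels=int(cfg["base_channels"]),
                    kernel_size=int(cfg["kernel_size"]), leaky_slope=float(cfg["leaky_slope"]),
                    patch=bool(cfg["patch"]), segment_len=int(cfg["segment_len"]),
                    seed=int(cfg["seed"])))
            arrays = []
            i = 0
            while f"{name}__{i}" in f:
                arrays.append(f[f"{name}__{i}"])
                i += 1
            model.load_state_arrays(arrays)
            models[name] = model
    return models, meta.get("extra", {})
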