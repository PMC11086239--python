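"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps an
ndarray (float64 by default, float32 selectable for CPU-bound training) and
remembers how it was produced, so a single backward sweep over the
topologically sorted tape yields exact gradients.  Backward closures take the
output gradient as an argument and never reference their own output tensor,
keeping the graph acyclic so memory is reclaimed by reference counting alone.  Only the operations needed
by the CNN-BiLSTM generators, the PatchGAN discriminators and the training
losses are implemented: broadcast-aware arithmetic, matmul, the usual
pointwise nonlinearities, reductions, shape ops, strided 1-D convolution and
max-pooling.  Adam lives here too since it only touches parameter tensors.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "conv1d",
    "maxpool1d",
    "no_grad",
    "Adam",
    "set_default_dtype",
    "get_default_dtype",
]

_GRAD_ENABLED = True
_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the float dtype new tensors are cast to (float64 or float32).

    float64 is the default; float32 roughly halves memory traffic for
    CPU-bound training runs.
    """
    global _DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = dtype.type


def get_default_dtype():
    return _DTYPE


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes numpy broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_gown", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents: tuple = (), requires_grad: bool | None = None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self._gown = False  # whether self.grad is an owned (mutable) buffer
        self._backward: Callable[[], None] | None = None
        self._parents = parents if _GRAD_ENABLED else ()
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in self._parents)
        self.requires_grad = requires_grad and _GRAD_ENABLED
        if not self.requires_grad:
            self._parents = ()

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        # copy-on-write: the first contribution is stored by reference (it is
        # never mutated upstream once written), later ones force an owned buffer
        if self.grad is None:
            self.grad = g
            self._gown = False
        elif self._gown:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._gown = True

    def _accumulate_at(self, idx, g: np.ndarray) -> None:
        """Scatter-add `g` into the gradient at basic-slice index `idx`."""
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
            self._gown = True
        elif not self._gown:
            self.grad = self.grad.copy()
            self._gown = True
        self.grad[idx] += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs contain thousands of LSTM nodes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        self._gown = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accumulate(g * p * self.data ** (p - 1.0))
            out._backward = _bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g)
            out._backward = _bw
        return out

    # -- pointwise nonlinearities -----------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic
        out = Tensor(y, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)
        out = Tensor(self.data * scale, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * scale)
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * sign)
        return out

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through only inside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def _bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, shape):
        out = Tensor(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate_at(idx, g)
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'none'})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


def tensor(x) -> Tensor:
    """Wrap an array-like as a constant (non-parameter) tensor."""
    return _as_tensor(x)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        nd = out.ndim

        def _bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * nd
                    sl[axis] = slice(a, b)
                    t._accumulate(g[tuple(sl)])
        out._backward = _bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Strided 1-D cross-correlation.

    x: (B, C_in, L); w: (C_out, C_in, K); b: (C_out,).
    Output length = (L + 2*padding - K) // stride + 1.
    """
    B, C, L = x.shape
    Co, Ci, K = w.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride, :]
    Lout = win.shape[2]
    # im2col: one contiguous copy, then plain BLAS matmuls throughout
    col = win.transpose(0, 2, 1, 3).reshape(B * Lout, C * K)
    w_mat = w.data.reshape(Co, C * K)
    out_mat = col @ w_mat.T                          # (B*Lout, Co)
    if b is not None:
        out_mat += b.data
    out_data = out_mat.reshape(B, Lout, Co).transpose(0, 2, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents)
    if out.requires_grad:
        def _bw(g):
            go = g.transpose(0, 2, 1).reshape(B * Lout, Co)
            if w.requires_grad:
                w._accumulate((go.T @ col).reshape(Co, C, K))
            if b is not None and b.requires_grad:
                b._accumulate(go.sum(axis=0))
            if x.requires_grad:
                gcol = (go @ w_mat).reshape(B, Lout, C, K).transpose(0, 2, 1, 3)
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[:, :, k:k + stride * Lout:stride] += gcol[:, :, :, k]
                x._accumulate(gxp[:, :, padding:padding + L] if padding else gxp)
        out._backward = _bw
    return out


def maxpool1d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping max pooling along the last axis (length must divide)."""
    B, C, L = x.shape
    if L % size:
        raise ValueError(f"length {L} not divisible by pool size {size}")
    blocks = x.data.reshape(B, C, L // size, size)
    arg = blocks.argmax(axis=3)
    out = Tensor(blocks.max(axis=3), (x,))
    if out.requires_grad:
        def _bw(g):
            gx = np.zeros_like(blocks)
            np.put_along_axis(gx, arg[..., None], g[..., None], axis=3)
            x._accumulate(gx.reshape(B, C, L))
        out._backward = _bw
    return out


def avgpool_to(x: Tensor, n_out: int) -> Tensor:
    """Average-pool the last axis down to exactly `n_out` positions."""
    B, C, L = x.shape
    if L % n_out:
        raise ValueError(f"length {L} not divisible into {n_out} patches")
    return x.reshape((B, C, n_out, L // n_out)).mean(axis=3)


class Adam:
    """Adam over a flat list of parameter tensors (Kingma-Ba defaults)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad ** 2
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
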