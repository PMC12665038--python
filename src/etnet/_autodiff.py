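"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the pair classifier needs (dense and
convolutional layers, multi-head attention with a relative-position bias,
layer normalization, pooling) plus an Adam optimizer. Values are float64;
all computation is deterministic given fixed inputs and parameters.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph walk ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ---------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.data.shape))
        return Tensor(out_data, parents=(self, other), backward=bw)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))
        return Tensor(out_data, parents=(self,), backward=bw)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))
        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            self._accum(g.swapaxes(a, b))
        return Tensor(self.data.swapaxes(a, b), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        return Tensor(out_data, parents=(self,), backward=bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)
        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)
        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)
        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))
        return Tensor(s, parents=(self,), backward=bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))
        return Tensor(s, parents=(self,), backward=bw)

    # -- linear algebra --------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, other.data.swapaxes(-1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(self.data.swapaxes(-1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))
        return Tensor(out_data, parents=(self, other), backward=bw)

    __matmul__ = matmul


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def unfold(x: Tensor, kernel: int, pad: int) -> Tensor:
    """Extract sliding windows: (B, L, C) -> (B, L + 2*pad - kernel + 1, kernel*C)."""
    B, L, C = x.data.shape
    padded = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    Lout = L + 2 * pad - kernel + 1
    idx = np.arange(kernel)[None, :] + np.arange(Lout)[:, None]  # (Lout, kernel)
    out_data = padded[:, idx, :].reshape(B, Lout, kernel * C)

    def bw(g):
        g4 = g.reshape(B, Lout, kernel, C)
        gpad = np.zeros_like(padded)
        np.add.at(gpad, (slice(None), idx), g4)
        x._accum(gpad[:, pad:pad + L, :])
    return Tensor(out_data, parents=(x,), backward=bw)


def maxpool1d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping max pooling along axis 1 of (B, L, C)."""
    B, L, C = x.data.shape
    if L % factor:
        raise ValueError(f"length {L} not divisible by pool factor {factor}")
    blocks = x.data.reshape(B, L // factor, factor, C)
    arg = blocks.argmax(axis=2)
    out_data = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def bw(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, arg[:, :, None, :], g[:, :, None, :], axis=2)
        x._accum(gb.reshape(B, L, C))
    return Tensor(out_data, parents=(x,), backward=bw)


def take(param: Tensor, idx: np.ndarray) -> Tensor:
    """Gather ``param[:, idx]`` from a 2-D table (scatter-add backward)."""
    if param.data.ndim != 2:
        raise ValueError("take expects a 2-D parameter table")
    out_data = param.data[:, idx]

    def bw(g):
        full = np.zeros_like(param.data)
        np.add.at(full, (slice(None), idx), g)
        param._accum(full)
    return Tensor(out_data, parents=(param,), backward=bw)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centered * inv * gain + bias


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
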