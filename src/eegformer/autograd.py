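"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The whole network in this package (depth-wise convolutions, the three
self-attention stages and the CNN decoder) is expressed with the small set
of differentiable primitives defined here.  The engine is deliberately
compact: float64 everywhere, dynamic graphs of closures, topological-order
backward.  Every primitive's gradient is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
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
    """An N-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (K blocks x stages)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    t.grad = g if t.grad is None else t.grad + g


# -- primitives -------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _wrap(a)
    if isinstance(exponent, Tensor):
        raise TypeError("only scalar exponents are supported")
    data = a.data ** exponent

    def backward(g):
        _accum(a, _unbroadcast(g * exponent * a.data ** (exponent - 1.0),
                               a.data.shape))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def exp(a) -> Tensor:
    a = _wrap(a)
    data = np.exp(a.data)

    def backward(g):
        _accum(a, g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)
    data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _make(data, (a,), backward)


def absolute(a) -> Tensor:
    """|a| with the subgradient sign(a) at 0 (as used for L1 penalties)."""
    a = _wrap(a)
    data = np.abs(a.data)

    def backward(g):
        _accum(a, g * np.sign(a.data))

    return _make(data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        _accum(a, g.transpose(inv))

    return _make(data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = _wrap(a)
    data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        _accum(a, full)

    return _make(data, (a,), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(data, ts, backward)


def broadcast_to(a, shape) -> Tensor:
    a = _wrap(a)
    data = np.broadcast_to(a.data, shape)

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))

    return _make(data.copy(), (a,), backward)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = _wrap(a)
    phi = 0.5 * (1.0 + erf(a.data * _INV_SQRT2))
    data = a.data * phi

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data ** 2)
        _accum(a, g * (phi + a.data * pdf))

    return _make(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        inner = (g * data).sum(axis=axis, keepdims=True)
        _accum(a, data * (g - inner))

    return _make(data, (a,), backward)


def layer_norm(a, axis: int = -1, eps: float = 1e-5) -> Tensor:
    """Normalize to zero mean / unit variance along `axis` (no affine part;
    learnable gain and bias, when wanted, are applied by the caller)."""
    a = _wrap(a)
    mu = a.data.mean(axis=axis, keepdims=True)
    xc = a.data - mu
    var = (xc ** 2).mean(axis=axis, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    data = xc * inv

    def backward(g):
        gm = g.mean(axis=axis, keepdims=True)
        gx = (g * data).mean(axis=axis, keepdims=True)
        _accum(a, inv * (g - gm - data * gx))

    return _make(data, (a,), backward)


def take_per_row(p, idx: np.ndarray) -> Tensor:
    """out[i] = p[i, idx[i]] — selects each row's true-class entry."""
    p = _wrap(p)
    idx = np.asarray(idx, dtype=np.intp)
    rows = np.arange(p.data.shape[0])
    data = p.data[rows, idx]

    def backward(g):
        full = np.zeros_like(p.data)
        full[rows, idx] = g
        _accum(p, full)

    return _make(data, (p,), backward)


def clip_min(a, lo: float) -> Tensor:
    """max(a, lo); gradient passes only where a > lo (log-prob guard)."""
    a = _wrap(a)
    data = np.maximum(a.data, lo)

    def backward(g):
        _accum(a, g * (a.data > lo))

    return _make(data, (a,), backward)


# -- convolution primitives --------------------------------------------------

def conv1d_bank(x, w) -> Tensor:
    """Bank of C length-k filters applied to every row of x.

    x: (..., L)  ->  (..., C, L-k+1).  One input map, C output maps; the
    same bank is shared across all leading (batch/channel) axes.
    """
    x, w = _wrap(x), _wrap(w)
    k = w.data.shape[1]
    xs = sliding_window_view(x.data, k, axis=-1)        # (..., Lout, k)
    data = np.einsum("...ik,ck->...ci", xs, w.data)

    def backward(g):
        gw = np.einsum("...ik,...ci->...ck", xs, g)
        gw = gw.sum(axis=tuple(range(gw.ndim - 2)))
        pad = [(0, 0)] * (g.ndim - 1) + [(k - 1, k - 1)]
        gp = np.pad(g, pad)                             # (..., C, Lout+2k-2)
        gs = sliding_window_view(gp, k, axis=-1)        # (..., C, L, k)
        gx = np.einsum("...cik,ck->...i", gs, w.data[:, ::-1])
        _accum(x, _unbroadcast(gx, x.data.shape))
        _accum(w, gw)

    return _make(data, (x, w), backward)


def conv1d_depthwise(x, w) -> Tensor:
    """Per-map (depth-wise) 1D convolution: map c gets its own filter.

    x: (..., C, L), w: (C, k)  ->  (..., C, L-k+1).  No cross-map mixing.
    """
    x, w = _wrap(x), _wrap(w)
    k = w.data.shape[1]
    xs = sliding_window_view(x.data, k, axis=-1)        # (..., C, Lout, k)
    data = np.einsum("...cik,ck->...ci", xs, w.data)

    def backward(g):
        gw = np.einsum("...cik,...ci->...ck", xs, g)
        gw = gw.sum(axis=tuple(range(gw.ndim - 2)))
        pad = [(0, 0)] * (g.ndim - 1) + [(k - 1, k - 1)]
        gp = np.pad(g, pad)
        gs = sliding_window_view(gp, k, axis=-1)        # (..., C, L, k)
        gx = np.einsum("...cik,ck->...ci", gs, w.data[:, ::-1])
        _accum(x, _unbroadcast(gx, x.data.shape))
        _accum(w, gw)

    return _make(data, (x, w), backward)


# -- parameters, modules, optimizer ------------------------------------------

class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight parameter container with recursive discovery."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def visit(obj, name):
            if isinstance(obj, Parameter):
                out.setdefault(name, obj)
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    visit(v, f"{name}.{k}" if name else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    visit(v, f"{name}.{i}")
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    visit(v, f"{name}.{k}")

        visit(self, prefix)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
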