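"""Reverse-mode automatic differentiation over numpy arrays.

The models in this package are small 1-D convolutional / recurrent networks
trained on CPU.  This module provides a tape-based autodiff engine with
exactly the operator set those models need: broadcasting arithmetic, matrix
multiplication, 1-D convolution and average pooling, the usual pointwise
nonlinearities, reductions, concatenation/stacking, and (fancy) indexing.

Gradients flow only through :class:`Tensor` objects; plain numpy arrays and
scalars entering an operation are treated as constants.  ``Parameter`` marks
trainable leaves.  Tensors are float64 by default; :func:`use_dtype` can
switch a region of code (e.g. a training run) to float32.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

_DTYPE = np.float64


def default_dtype() -> np.dtype:
    return _DTYPE


@contextmanager
def use_dtype(dtype):
    """Temporarily change the dtype new tensors are created with.

    float64 is the default (and what every numerical-equivalence test
    runs under); float32 roughly halves the cost of training runs.
    """
    global _DTYPE
    previous = _DTYPE
    _DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DTYPE = previous

__all__ = [
    "Tensor", "Parameter", "Module",
    "add", "sub", "mul", "div", "neg", "matmul",
    "exp", "log", "tanh", "sigmoid", "relu", "leaky_relu", "sqrt", "absolute",
    "sum_", "mean_", "concat", "stack", "reshape", "transpose", "getitem",
    "broadcast_to", "conv1d", "avg_pool1d", "log_softmax",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _vjps: tuple = ()):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        # keep the tape only where gradients can flow
        self._parents = _parents if self.requires_grad else ()
        self._vjps = _vjps if self.requires_grad else ()
        self.grad: np.ndarray | None = None

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf's ``.grad``."""
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep: recurrent loops)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                pg = vjp(g)
                acc = grads.get(id(parent))
                grads[id(parent)] = pg if acc is None else acc + pg

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other): return add(self, other)
    def __radd__(self, other): return add(other, self)
    def __sub__(self, other): return sub(self, other)
    def __rsub__(self, other): return sub(other, self)
    def __mul__(self, other): return mul(self, other)
    def __rmul__(self, other): return mul(other, self)
    def __truediv__(self, other): return div(self, other)
    def __rtruediv__(self, other): return div(other, self)
    def __neg__(self): return neg(self)
    def __matmul__(self, other): return matmul(self, other)
    def __getitem__(self, idx): return getitem(self, idx)

    def reshape(self, *shape): return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])
    def transpose(self, *axes): return transpose(self, axes)
    def sum(self, axis=None, keepdims=False): return sum_(self, axis, keepdims)
    def mean(self, axis=None, keepdims=False): return mean_(self, axis, keepdims)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(a.data + b.data, _parents=(a, b),
                  _vjps=(lambda g: _unbroadcast(g, a.data.shape),
                         lambda g: _unbroadcast(g, b.data.shape)))


def sub(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(a.data - b.data, _parents=(a, b),
                  _vjps=(lambda g: _unbroadcast(g, a.data.shape),
                         lambda g: _unbroadcast(-g, b.data.shape)))


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(a.data * b.data, _parents=(a, b),
                  _vjps=(lambda g: _unbroadcast(g * b.data, a.data.shape),
                         lambda g: _unbroadcast(g * a.data, b.data.shape)))


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(a.data / b.data, _parents=(a, b),
                  _vjps=(lambda g: _unbroadcast(g / b.data, a.data.shape),
                         lambda g: _unbroadcast(-g * a.data / b.data ** 2, b.data.shape)))


def neg(a) -> Tensor:
    a = astensor(a)
    return Tensor(-a.data, _parents=(a,), _vjps=(lambda g: -g,))


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data @ b.data

    def vjp_a(g):
        return _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)

    def vjp_b(g):
        return _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)

    return Tensor(out, _parents=(a, b), _vjps=(vjp_a, vjp_b))


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def exp(a) -> Tensor:
    a = astensor(a)
    out = np.exp(a.data)
    return Tensor(out, _parents=(a,), _vjps=(lambda g: g * out,))


def log(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.log(a.data), _parents=(a,), _vjps=(lambda g: g / a.data,))


def sqrt(a) -> Tensor:
    a = astensor(a)
    out = np.sqrt(a.data)
    return Tensor(out, _parents=(a,), _vjps=(lambda g: g * 0.5 / out,))


def tanh(a) -> Tensor:
    a = astensor(a)
    out = np.tanh(a.data)
    return Tensor(out, _parents=(a,), _vjps=(lambda g: g * (1.0 - out ** 2),))


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out = expit(a.data)
    return Tensor(out, _parents=(a,), _vjps=(lambda g: g * out * (1.0 - out),))


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    return Tensor(np.where(mask, a.data, 0.0), _parents=(a,),
                  _vjps=(lambda g: g * mask,))


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    """Elementwise max(slope * x, x) for 0 < slope < 1."""
    a = astensor(a)
    mask = a.data > 0
    factor = np.where(mask, 1.0, slope)
    return Tensor(a.data * factor, _parents=(a,), _vjps=(lambda g: g * factor,))


def absolute(a) -> Tensor:
    a = astensor(a)
    sign = np.sign(a.data)
    return Tensor(np.abs(a.data), _parents=(a,), _vjps=(lambda g: g * sign,))


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        g2 = g
        if not keepdims:
            g2 = np.expand_dims(g2, axis)
        return np.broadcast_to(g2, a.data.shape).copy()

    return Tensor(out, _parents=(a,), _vjps=(vjp,))


def mean_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    count = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return div(sum_(a, axis, keepdims), float(count))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    return Tensor(a.data.reshape(shape), _parents=(a,),
                  _vjps=(lambda g: g.reshape(a.data.shape),))


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return Tensor(a.data.transpose(axes), _parents=(a,),
                  _vjps=(lambda g: g.transpose(inv),))


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def make_vjp(i):
        return lambda g: np.split(g, splits, axis=axis)[i]

    return Tensor(np.concatenate([t.data for t in ts], axis=axis),
                  _parents=tuple(ts), _vjps=tuple(make_vjp(i) for i in range(len(ts))))


def stack(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [astensor(t) for t in tensors]

    def make_vjp(i):
        return lambda g: np.take(g, i, axis=axis)

    return Tensor(np.stack([t.data for t in ts], axis=axis),
                  _parents=tuple(ts), _vjps=tuple(make_vjp(i) for i in range(len(ts))))


def _needs_scatter_add(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return any(isinstance(i, (list, np.ndarray)) and np.asarray(i).dtype != bool
               for i in items)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    scatter = _needs_scatter_add(idx)  # integer-array indices may repeat

    def vjp(g):
        ga = np.zeros_like(a.data)
        if scatter:
            np.add.at(ga, idx, g)
        else:
            ga[idx] += g
        return ga

    return Tensor(a.data[idx], _parents=(a,), _vjps=(vjp,))


def broadcast_to(a, shape) -> Tensor:
    """Broadcast ``a`` to ``shape``; gradient sums over the broadcast axes."""
    a = astensor(a)
    return Tensor(np.broadcast_to(a.data, shape), _parents=(a,),
                  _vjps=(lambda g: _unbroadcast(g, a.data.shape),))


def log_softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    a = astensor(a)
    shift = a.data.max(axis=axis, keepdims=True)  # constant under differentiation
    z = sub(a, shift)
    return sub(z, log(sum_(exp(z), axis=axis, keepdims=True)))


# ---------------------------------------------------------------------------
# 1-D convolution / pooling (inputs laid out [batch, channels, length])
# ---------------------------------------------------------------------------

def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """[B, C, L] -> [B, C, L_out, k] sliding windows (a view)."""
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::stride, :]


def conv1d(x, w, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of ``x`` [B, Cin, L] with kernels ``w`` [Cout, Cin, k]."""
    x, w = astensor(x), astensor(w)
    B, Cin, L = x.data.shape
    Cout, Cin2, k = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    Lp = xp.shape[2]
    Lout = (Lp - k) // stride + 1
    if Lout <= 0:
        raise ValueError(f"kernel {k} does not fit input of length {Lp}")
    win = _windows(xp, k, stride)                                   # [B,Cin,Lout,k]
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * Lout, Cin * k)
    wmat = w.data.reshape(Cout, Cin * k)
    out = (cols @ wmat.T).reshape(B, Lout, Cout).transpose(0, 2, 1)

    def vjp_x(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Lout, Cout)
        gcols = (gmat @ wmat).reshape(B, Lout, Cin, k)
        gx = np.zeros((B, Cin, Lp), dtype=np.result_type(g.dtype, wmat.dtype))
        for j in range(k):
            gx[:, :, j:j + stride * Lout:stride] += gcols[:, :, :, j].transpose(0, 2, 1)
        return gx[:, :, padding:Lp - padding] if padding else gx

    def vjp_w(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Lout, Cout)
        return (gmat.T @ cols).reshape(Cout, Cin, k)

    return Tensor(out, _parents=(x, w), _vjps=(vjp_x, vjp_w))


def avg_pool1d(x, k: int, stride: int | None = None) -> Tensor:
    """Non-overlapping (by default) average pooling over the last axis."""
    x = astensor(x)
    stride = k if stride is None else stride
    B, C, L = x.data.shape
    Lout = (L - k) // stride + 1
    win = _windows(x.data, k, stride)
    out = win.mean(axis=3)

    def vjp(g):
        gx = np.zeros_like(x.data)
        for j in range(k):
            gx[:, :, j:j + stride * Lout:stride] += g / k
        return gx

    return Tensor(out, _parents=(x,), _vjps=(vjp,))


# ---------------------------------------------------------------------------
# module/parameter plumbing
# ---------------------------------------------------------------------------

class Module:
    """Base class providing recursive parameter discovery.

    Submodules, parameters, and lists thereof are found in attribute
    definition order, giving a stable naming scheme for checkpoints.
    """

    def named_parameters(self, prefix: str = ""):
        def walk(value, path):
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(item, f"{path}.{i}")

        for name, value in vars(self).items():
            yield from walk(value, f"{prefix}{name}")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None
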