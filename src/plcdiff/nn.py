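"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Everything runs in float64. The engine supports exactly the operations the
denoising network needs: broadcast arithmetic, a handful of nonlinearities,
reductions, reshape/transpose, embedding lookup, linear layers, fused
layer-norm and softmax, and two-operand einsum contractions. Gradients are
accumulated by topological traversal of the recorded tape.

A global ``no_grad`` switch disables tape construction for inference
(sampling touches the model thousands of times and never needs gradients).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterator, Sequence

import numpy as np

_grad_enabled: bool = True


@contextlib.contextmanager
def no_grad() -> Iterator[None]:
    """Context manager disabling gradient tape recording."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph mechanics ---------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, prev: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    tracked = tuple(p for p in prev if p.requires_grad)
    if tracked and _grad_enabled:
        out.requires_grad = True
        out._prev = tracked
    return out


# -- primitive ops ---------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data + b.data, (a, b))
    if out.requires_grad:
        def _bw():
            if a.requires_grad:
                a._accumulate(out.grad)
            if b.requires_grad:
                b._accumulate(out.grad)
        out._backward = _bw
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data * b.data, (a, b))
    if out.requires_grad:
        def _bw():
            if a.requires_grad:
                a._accumulate(out.grad * b.data)
            if b.requires_grad:
                b._accumulate(out.grad * a.data)
        out._backward = _bw
    return out


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = _make(a.data ** exponent, (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad * exponent * a.data ** (exponent - 1))
        out._backward = _bw
    return out


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.exp(a.data), (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad * out.data)
        out._backward = _bw
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(y, (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad * out.data * (1.0 - out.data))
        out._backward = _bw
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.maximum(a.data, 0.0), (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad * (a.data > 0.0))
        out._backward = _bw
    return out


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = _make(a.data.sum(axis=axis, keepdims=keepdims), (a,))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape))
        out._backward = _bw
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = _make(a.data.reshape(shape), (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad.reshape(a.data.shape))
        out._backward = _bw
    return out


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out = _make(np.transpose(a.data, axes), (a,))
    if out.requires_grad:
        inv = np.argsort(axes)
        def _bw():
            a._accumulate(np.transpose(out.grad, inv))
        out._backward = _bw
    return out


def einsum2(spec: str, a, b) -> Tensor:
    """Two-operand einsum.

    Constraint (asserted by construction, not at runtime): every index of
    each operand appears in the other operand or in the output, and no index
    repeats within one operand. Under that constraint the gradient of each
    operand is itself a two-operand einsum with subscripts swapped.
    """
    a, b = as_tensor(a), as_tensor(b)
    lhs, out_s = spec.split("->")
    in_a, in_b = lhs.split(",")
    out = _make(np.einsum(spec, a.data, b.data), (a, b))
    if out.requires_grad:
        def _bw():
            if a.requires_grad:
                a._accumulate(np.einsum(f"{out_s},{in_b}->{in_a}", out.grad, b.data))
            if b.requires_grad:
                b._accumulate(np.einsum(f"{out_s},{in_a}->{in_b}", out.grad, a.data))
        out._backward = _bw
    return out


def linear_op(x, w: "Tensor", b: "Tensor | None") -> Tensor:
    """y[..., o] = sum_i x[..., i] w[i, o] (+ b[o])."""
    x = as_tensor(x)
    y = x.data @ w.data
    if b is not None:
        y = y + b.data
    prev = (x, w) if b is None else (x, w, b)
    out = _make(y, prev)
    if out.requires_grad:
        def _bw():
            g = out.grad
            if x.requires_grad:
                x._accumulate(g @ w.data.T)
            if w.requires_grad:
                gw = g.reshape(-1, g.shape[-1])
                xw = x.data.reshape(-1, x.data.shape[-1])
                w._accumulate(xw.T @ gw)
            if b is not None and b.requires_grad:
                b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
        out._backward = _bw
    return out


def embedding_op(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``table[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)
    out = _make(table.data[idx], (table,))
    if out.requires_grad:
        def _bw():
            g = np.zeros_like(table.data)
            np.add.at(g, idx, out.grad)
            table._accumulate(g)
        out._backward = _bw
    return out


def layer_norm_op(x, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with learned affine parameters."""
    x = as_tensor(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = _make(xhat * gamma.data + beta.data, (x, gamma, beta))
    if out.requires_grad:
        def _bw():
            g = out.grad
            n = x.data.shape[-1]
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).reshape(-1, n).sum(axis=0))
            if beta.requires_grad:
                beta._accumulate(g.reshape(-1, n).sum(axis=0))
            if x.requires_grad:
                gx_hat = g * gamma.data
                gx = inv * (
                    gx_hat
                    - gx_hat.mean(axis=-1, keepdims=True)
                    - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
                )
                x._accumulate(gx)
        out._backward = _bw
    return out


def softmax_op(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _make(y, (x,))
    if out.requires_grad:
        def _bw():
            g = out.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))
        out._backward = _bw
    return out


# -- modules ---------------------------------------------------------------


class Module:
    """Parameter container with recursive named-parameter discovery."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for key, value in vars(self).items():
            path = f"{prefix}{key}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{path}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _param(shape, rng: np.random.Generator | None, scale: float | None = None) -> Tensor:
    if rng is None or scale == 0.0:
        data = np.zeros(shape)
    else:
        if scale is None:
            fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
            scale = 1.0 / np.sqrt(fan_in)
        data = rng.normal(0.0, scale, size=shape)
    t = Tensor(data)
    t.requires_grad = True  # parameters ignore the no_grad state at build time
    return t


class Linear(Module):
    """Affine map on the last axis; ``zero_init`` gives exact-zero output."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None,
                 zero_init: bool = False, bias: bool = True):
        self.w = _param((d_in, d_out), None if zero_init else rng)
        self.b = _param((d_out,), None) if bias else None

    def __call__(self, x) -> Tensor:
        return linear_op(x, self.w, self.b)


class LayerNorm(Module):
    def __init__(self, dim: int):
        g = Tensor(np.ones(dim)); g.requires_grad = True
        b = Tensor(np.zeros(dim)); b.requires_grad = True
        self.g, self.b = g, b

    def __call__(self, x) -> Tensor:
        return layer_norm_op(x, self.g, self.b)


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.table = _param((n_vocab, dim), rng, scale=0.02)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding_op(self.table, idx)


# -- optimization ----------------------------------------------------------


class Adam:
    """Adam with linear learning-rate warm-up handled by the caller."""

    def __init__(self, params: Sequence[Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class EMA:
    """Exponential moving average shadow of a parameter list."""

    def __init__(self, params: Sequence[Tensor], decay: float = 0.999):
        self.decay = decay
        self.shadow = [p.data.copy() for p in params]

    def update(self, params: Sequence[Tensor]) -> None:
        d = self.decay
        for s, p in zip(self.shadow, params):
            s *= d
            s += (1.0 - d) * p.data


@contextlib.contextmanager
def swap_params(params: Sequence[Tensor], arrays: Sequence[np.ndarray]) -> Iterator[None]:
    """Temporarily replace parameter values (e.g. with an EMA snapshot)."""
    saved = [p.data for p in params]
    for p, a in zip(params, arrays):
        p.data = a
    try:
        yield
    finally:
        for p, s in zip(params, saved):
            p.data = s


def perturb_parameters(module: Module, rng: np.random.Generator, scale: float = 0.1) -> None:
    """Add Gaussian noise to every parameter.

    Useful for exercising a freshly built model whose residual branches are
    zero-initialized (and whose output would otherwise be identically zero).
    """
    for _, p in module.named_parameters():
        p.data = p.data + rng.normal(0.0, scale, size=p.data.shape)
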