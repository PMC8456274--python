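"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the 1-D convolutional GAN in
:mod:`ldims.stabilizer` on a single CPU: a :class:`Tensor` wrapping a float32
array, a tape of primitive ops with hand-written vector-Jacobian products,
and Adam.  Convolutions are lowered to BLAS matmuls via im2col; their input
gradient is itself a correlation with the flipped kernel, so the backward
pass stays in BLAS too.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

__all__ = ["Tensor", "Adam", "conv1d", "bce_with_logits", "concat"]


def _noop() -> None:
    return None


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] = _noop
        if not _GRAD_ENABLED[0]:
            _prev, requires_grad = (), False
        self._prev = _prev
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self) -> None:
        topo, seen = [], set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            t._backward()
            # break closure<->tensor reference cycles so graph memory is
            # reclaimed immediately instead of waiting for the cycle collector
            t._backward = _noop
            t._prev = ()

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        if out.requires_grad:
            out._backward = bw
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        if out.requires_grad:
            out._backward = bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        if out.requires_grad:
            out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        if out.requires_grad:
            out._backward = bw
        return out

    def leaky_relu(self, alpha: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data),
                     _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0, alpha).astype(np.float32))

        if out.requires_grad:
            out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -30, 30)))
        out = Tensor(s, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        if out.requires_grad:
            out._backward = bw
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * np.sign(self.data))

        if out.requires_grad:
            out._backward = bw
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        if out.requires_grad:
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        if out.requires_grad:
            out._backward = bw
        return out

    def stride_slice(self, step: int) -> "Tensor":
        """x[:, :, ::step] with scatter backward (stride-``step`` downsampling)."""
        out = Tensor(self.data[:, :, ::step], _prev=(self,))

        def bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[:, :, ::step] = out.grad
                self._accum(g)

        if out.requires_grad:
            out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    if out.requires_grad:
        out._backward = bw
    return out


def _shift_stack(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, L) zero-padded to 'same' -> (N, K*C, L) stacked shifted slices.

    Row block ``kk`` holds the input shifted so that output position ``l``
    sees input position ``l + kk - k//2``; contiguous copies keep this cheap.
    """
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    n, c, lp = xp.shape
    l = lp - 2 * pad
    out = np.empty((n, k * c, l), dtype=np.float32)
    for kk in range(k):
        out[:, kk * c:(kk + 1) * c, :] = xp[:, :, kk:kk + l]
    return out


def _w2(w: np.ndarray) -> np.ndarray:
    """(O, C, K) -> (O, K*C) matching the _shift_stack row layout."""
    o, c, k = w.shape
    return np.ascontiguousarray(w.transpose(0, 2, 1)).reshape(o, k * c)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 1-D convolution (correlation): x (N,C,L), w (O,C,K), b (O,)."""
    n, c, l = x.data.shape
    o, c2, k = w.data.shape
    if c != c2 or k % 2 == 0:
        raise ValueError("channel mismatch or even kernel")
    stack = _shift_stack(x.data, k)                       # (N, K*C, L)
    y = np.matmul(_w2(w.data), stack) + b.data[:, None]   # (N, O, L)
    out = Tensor(y, _prev=(x, w, b))

    def bw():
        gy = out.grad                                     # (N, O, L)
        if w.requires_grad:
            gw2 = np.matmul(gy, stack.transpose(0, 2, 1)).sum(axis=0)  # (O, K*C)
            w._accum(gw2.reshape(o, k, c).transpose(0, 2, 1))
        if b.requires_grad:
            b._accum(gy.sum(axis=(0, 2)))
        if x.requires_grad:
            # dL/dx is a 'same' correlation of gy with the flipped kernel,
            # channels and filters swapped -> reuse the shift-stack/BLAS path
            wt = w.data[:, :, ::-1].transpose(1, 0, 2)    # (C, O, K)
            gstack = _shift_stack(gy, k)                  # (N, K*O, L)
            x._accum(np.matmul(_w2(wt), gstack))          # (N, C, L)

    if out.requires_grad:
        out._backward = bw
    return out


def bce_with_logits(logits: Tensor, target: float) -> Tensor:
    """Mean binary cross-entropy with a constant scalar target (0 or 1)."""
    z = logits.data
    loss = np.maximum(z, 0) - target * z + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), _prev=(logits,))

    def bw():
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accum(out.grad * (s - target) / z.size)

    if out.requires_grad:
        out._backward = bw
    return out


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 2e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

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
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
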