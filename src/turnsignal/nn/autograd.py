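"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``backward()`` on a scalar loss walks the tape in reverse topological order and
accumulates gradients.  The op set is exactly what the sequence classifiers in
:mod:`turnsignal.nn` need: broadcast-aware arithmetic, matmul, the usual
pointwise nonlinearities, axis reductions, reshape/transpose/slicing/concat,
a strided 1-D convolution, and a fused softmax cross-entropy.

Float32 throughout; gradients are accumulated in the same dtype.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _prev=tuple(p for p in parents if p.requires_grad))
        if req:
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        def backward(g):
            self._accum(g.reshape(self.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    def softmax_last(self) -> "Tensor":
        """Softmax over the last axis (numerically stabilized)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=-1, keepdims=True)
            self._accum(s * (g - dot))

        return self._make(s, (self,), backward)

    # -- autodiff ---------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0, *sizes])

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req,
                 _prev=tuple(t for t in tensors if t.requires_grad))
    if req:
        out._backward = backward
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, dilation: int = 1,
           pad: tuple[int, int] = (0, 0)) -> Tensor:
    """1-D convolution (cross-correlation): (B,C,L) * (F,C,K) -> (B,F,L_out)."""
    B, C, L = x.shape
    F, C2, K = weight.shape
    assert C == C2, (C, C2)
    pl, pr = pad
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x.data
    Lp = xp.shape[2]
    span = (K - 1) * dilation + 1
    L_out = (Lp - span) // stride + 1
    s0, s1, s2 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(B, L_out, C, K), strides=(s0, s2 * stride, s1, s2 * dilation)
    ).reshape(B * L_out, C * K)
    cols = np.ascontiguousarray(cols)
    wmat = weight.data.reshape(F, C * K)
    out_data = (cols @ wmat.T).reshape(B, L_out, F).transpose(0, 2, 1)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None]

    def backward(g):
        g2 = g.transpose(0, 2, 1).reshape(B * L_out, F)
        if weight.requires_grad:
            weight._accum((g2.T @ cols).reshape(F, C, K))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = (g2 @ wmat).reshape(B, L_out, C, K)
            dxp = np.zeros((B, C, Lp), dtype=np.float32)
            for k in range(K):
                dxp[:, :, k * dilation : k * dilation + L_out * stride : stride] += \
                    dcols[:, :, :, k].transpose(0, 2, 1)
            x._accum(dxp[:, :, pl : Lp - pr] if (pl or pr) else dxp)

    parents = [x, weight] + ([bias] if bias is not None else [])
    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, requires_grad=req,
                 _prev=tuple(p for p in parents if p.requires_grad))
    if req:
        out._backward = backward
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted softmax cross-entropy, averaged with weight normalization.

    ``labels`` are integer class indices; ``class_weights`` (per class)
    default to ones.  The backward pass is the closed form
    ``w_i (softmax - onehot) / sum(w)``.
    """
    n, k = logits.shape
    labels = np.asarray(labels, dtype=np.int64)
    w = np.ones(k, dtype=np.float32) if class_weights is None else \
        np.asarray(class_weights, dtype=np.float32)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    logp = z[np.arange(n), labels] - lse
    wi = w[labels]
    wsum = wi.sum()
    loss = -(wi * logp).sum() / wsum

    def backward(g):
        p = np.exp(z - lse[:, None])
        p[np.arange(n), labels] -= 1.0
        logits._accum(g * p * (wi / wsum)[:, None])

    out = Tensor(np.float32(loss), requires_grad=logits.requires_grad,
                 _prev=(logits,) if logits.requires_grad else ())
    if logits.requires_grad:
        out._backward = backward
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Plain numpy softmax over the last axis (inference path)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
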