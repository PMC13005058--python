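"""Neural-network building blocks on the :mod:`turnsignal.nn.autograd` engine.

Conventions follow the time-series-classification literature: sequence inputs
are (batch, channels, length); convolutions are "same"-padded unless causal;
recurrent layers consume (batch, channels, length) and expose either the final
hidden state or the full output sequence for attention pooling.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, conv1d


class Module:
    """Base class: parameter discovery, train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in (self, *self.modules()):
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
                elif isinstance(v, (list, tuple)):
                    params.extend(p for p in v if isinstance(p, Tensor) and p.requires_grad)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def checksum(self) -> float:
        """Deterministic scalar fingerprint of the current weights."""
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)


class Linear(Module):
    def __init__(self, rng, n_in: int, n_out: int):
        super().__init__()
        self.w = Tensor(_kaiming(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """Same/causal/valid-padded 1-D convolution over (B, C, L)."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int,
                 dilation: int = 1, padding: str = "same"):
        super().__init__()
        self.kernel = kernel
        self.dilation = dilation
        span = (kernel - 1) * dilation
        if padding == "same":
            self.pad = (span // 2, span - span // 2)
        elif padding == "causal":
            self.pad = (span, 0)
        elif padding == "valid":
            self.pad = (0, 0)
        else:
            raise ValueError(f"unknown padding {padding!r}")
        self.w = Tensor(_kaiming(rng, (c_out, c_in, kernel), c_in * kernel),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, dilation=self.dilation, pad=self.pad)


class BatchNorm1d(Module):
    """Per-channel batch normalization over (B, C, L)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, c, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1), dtype=np.float32), requires_grad=True)
        self.run_mean = np.zeros((1, c, 1), dtype=np.float32)
        self.run_var = np.ones((1, c, 1), dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            self.run_mean = ((1 - self.momentum) * self.run_mean
                             + self.momentum * mu.data).astype(np.float32)
            self.run_var = ((1 - self.momentum) * self.run_var
                            + self.momentum * var.data).astype(np.float32)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.run_mean)) * ((Tensor(self.run_var) + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class ConvBlock(Module):
    """conv -> batchnorm -> ReLU, the FCN-for-TSC workhorse."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 padding: str = "same"):
        super().__init__()
        self.conv = Conv1d(rng, c_in, c_out, kernel, dilation, padding)
        self.bn = BatchNorm1d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, L) -> (B, C) mean over time."""
    return x.mean(axis=2)


def stack_time(steps: list[Tensor]) -> Tensor:
    """Stack a list of (B, H) step outputs into (B, L, H)."""
    b, h = steps[0].shape
    return concat([s.reshape(b, 1, h) for s in steps], axis=1)


class GRU(Module):
    """Single-layer GRU over (B, C, L); returns (outputs (B,L,H), last (B,H))."""

    def __init__(self, rng, c_in: int, hidden: int = 64):
        super().__init__()
        self.hidden = hidden
        self.wx = Tensor(_kaiming(rng, (c_in, 3 * hidden), c_in), requires_grad=True)
        self.wh = Tensor(_kaiming(rng, (hidden, 3 * hidden), hidden), requires_grad=True)
        self.b = Tensor(np.zeros(3 * hidden, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor):
        B, C, L = x.shape
        h = Tensor(np.zeros((B, self.hidden), dtype=np.float32))
        H = self.hidden
        outs = []
        for t in range(L):
            xt = x[:, :, t]
            gx = xt @ self.wx + self.b
            gh = h @ self.wh
            z = (gx[:, 0:H] + gh[:, 0:H]).sigmoid()
            r = (gx[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
            n = (gx[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
            h = (1.0 - z) * n + z * h
            outs.append(h)
        return stack_time(outs), h


class LSTM(Module):
    """Single-layer LSTM over (B, C, L); returns (outputs, last hidden)."""

    def __init__(self, rng, c_in: int, hidden: int = 64):
        super().__init__()
        self.hidden = hidden
        self.wx = Tensor(_kaiming(rng, (c_in, 4 * hidden), c_in), requires_grad=True)
        self.wh = Tensor(_kaiming(rng, (hidden, 4 * hidden), hidden), requires_grad=True)
        self.b = Tensor(np.zeros(4 * hidden, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor):
        B, C, L = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        c = Tensor(np.zeros((B, H), dtype=np.float32))
        outs = []
        for t in range(L):
            g = x[:, :, t] @ self.wx + h @ self.wh + self.b
            i = g[:, 0:H].sigmoid()
            f = g[:, H:2 * H].sigmoid()
            o = g[:, 2 * H:3 * H].sigmoid()
            u = g[:, 3 * H:].tanh()
            c = f * c + i * u
            h = o * c.tanh()
            outs.append(h)
        return stack_time(outs), h


class AdditiveAttention(Module):
    """Additive (Bahdanau-style) pooling over time: (B, L, H) -> (B, H)."""

    def __init__(self, rng, hidden: int, att_dim: int = 32):
        super().__init__()
        self.w = Tensor(_kaiming(rng, (hidden, att_dim), hidden), requires_grad=True)
        self.b = Tensor(np.zeros(att_dim, dtype=np.float32), requires_grad=True)
        self.v = Tensor(_kaiming(rng, (att_dim, 1), att_dim), requires_grad=True)

    def forward(self, seq: Tensor) -> Tensor:
        B, L, H = seq.shape
        scores = ((seq @ self.w + self.b).tanh() @ self.v).reshape(B, L)
        alpha = scores.softmax_last().reshape(B, L, 1)
        return (seq * alpha).sum(axis=1)


class MultiHeadAttention(Module):
    """Independent additive-attention heads, concatenated: (B,L,H) -> (B, n*H)."""

    def __init__(self, rng, hidden: int, heads: int = 4, att_dim: int = 16):
        super().__init__()
        self.heads = [AdditiveAttention(rng, hidden, att_dim) for _ in range(heads)]

    def forward(self, seq: Tensor) -> Tensor:
        return concat([h(seq) for h in self.heads], axis=1)


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention, mean-pooled over time."""

    def __init__(self, rng, hidden: int, d: int = 32):
        super().__init__()
        self.wq = Tensor(_kaiming(rng, (hidden, d), hidden), requires_grad=True)
        self.wk = Tensor(_kaiming(rng, (hidden, d), hidden), requires_grad=True)
        self.wv = Tensor(_kaiming(rng, (hidden, d), hidden), requires_grad=True)
        self.scale = 1.0 / math.sqrt(d)

    def forward(self, seq: Tensor) -> Tensor:
        q = seq @ self.wq
        k = seq @ self.wk
        v = seq @ self.wv
        att = ((q @ k.transpose((0, 2, 1))) * self.scale).softmax_last()
        return (att @ v).mean(axis=1)
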