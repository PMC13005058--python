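"""Reference sequence-classifier architectures for driving time series.

Three families are provided, mirroring the standard time-series-classification
toolbox: 1-D convolutional networks (``cnn1d``, ``tiny_fcn``,
``inception_lite``, ``inception_time_small``, ``resnet_tsc``), recurrent
networks (``gru``, ``lstm``, optionally with additive or multi-head attention
pooling), and temporal convolutional networks (``tcn``, ``tiny_tcn``, with
optional self-attention pooling).  Dual variants run two weight-independent
encoders (a trip branch and a turn branch) and merge the latent vectors by
concatenation or a learned sigmoid gate before a linear classification head.

These are deliberately compact instantiations of the named conventions —
TinyFCN is the classic 3-block fully-convolutional network (32/64/32 filters,
kernels 8/5/3) with global average pooling — sized for cohorts of hundreds of
trips rather than ImageNet-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autograd import Tensor, concat, softmax_probs
from .layers import (
    AdditiveAttention, BatchNorm1d, Conv1d, ConvBlock, Dropout, GRU, LSTM, Linear,
    Module, MultiHeadAttention, SelfAttention, global_avg_pool,
)

FAMILIES = (
    "cnn1d", "tiny_fcn", "inception_lite", "inception_time_small",
    "resnet_tsc", "gru", "lstm", "tcn", "tiny_tcn",
)
_CONV_FAMILIES = ("cnn1d", "tiny_fcn", "inception_lite", "inception_time_small", "resnet_tsc")
_RNN_FAMILIES = ("gru", "lstm")
_TCN_FAMILIES = ("tcn", "tiny_tcn")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description; ``build_model`` turns it into weights."""

    family: str = "tiny_fcn"
    attention: str = "none"  # none | single | multihead | self
    dual: bool = False
    fusion: str = "gated"  # concat | gated (dual only)
    in_channels: int = 10
    seq_len: int | tuple[int, int] = 1200
    dropout: float | None = None
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.attention not in ("none", "single", "multihead", "self"):
            raise ValueError(f"unknown attention {self.attention!r}")
        if self.attention in ("single", "multihead") and self.family not in _RNN_FAMILIES:
            raise ValueError("additive attention applies to recurrent families only")
        if self.attention == "self" and self.family not in _TCN_FAMILIES:
            raise ValueError("self-attention pooling applies to TCN families only")
        if self.fusion not in ("concat", "gated"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if not self.dual and self.in_channels not in (10, 20):
            raise ValueError("single-view models take 10 or 20 input channels")


# ---------------------------------------------------------------------------
# encoders: (B, C, L) -> (B, latent)
# ---------------------------------------------------------------------------

class _ConvEncoder(Module):
    def __init__(self, rng, c_in: int, widths, kernels):
        super().__init__()
        blocks = []
        c = c_in
        for w, k in zip(widths, kernels):
            blocks.append(ConvBlock(rng, c, w, k))
            c = w
        self.blocks = blocks
        self.latent_dim = c

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return global_avg_pool(x)


class _InceptionBlock(Module):
    def __init__(self, rng, c_in: int, branch_width: int, bottleneck: int | None):
        super().__init__()
        self.bottleneck = Conv1d(rng, c_in, bottleneck, 1) if bottleneck else None
        c = bottleneck or c_in
        self.branches = [Conv1d(rng, c, branch_width, k) for k in (3, 5, 9)]
        self.bn = BatchNorm1d(3 * branch_width)
        self.out_dim = 3 * branch_width

    def forward(self, x):
        if self.bottleneck is not None:
            x = self.bottleneck(x)
        y = concat([b(x) for b in self.branches], axis=1)
        return self.bn(y).relu()


class _InceptionEncoder(Module):
    def __init__(self, rng, c_in: int, n_blocks: int, branch_width: int,
                 bottleneck: int | None, residual: bool):
        super().__init__()
        self.blocks = []
        self.shortcuts = []
        c = c_in
        for _ in range(n_blocks):
            blk = _InceptionBlock(rng, c, branch_width, bottleneck)
            self.blocks.append(blk)
            self.shortcuts.append(Conv1d(rng, c, blk.out_dim, 1) if residual else None)
            c = blk.out_dim
        self.latent_dim = c

    def forward(self, x):
        for blk, sc in zip(self.blocks, self.shortcuts):
            y = blk(x)
            x = (y + sc(x)).relu() if sc is not None else y
        return global_avg_pool(x)


class _ResNetEncoder(Module):
    """Three residual blocks of triple conv (kernels 8/5/3), TSC convention."""

    def __init__(self, rng, c_in: int, widths=(32, 64, 64)):
        super().__init__()
        self.stages = []
        self.shortcuts = []
        c = c_in
        for w in widths:
            self.stages.append([
                ConvBlock(rng, c, w, 8), ConvBlock(rng, w, w, 5), ConvBlock(rng, w, w, 3),
            ])
            self.shortcuts.append(Conv1d(rng, c, w, 1))
            c = w
        self.latent_dim = c

    def forward(self, x):
        for stage, sc in zip(self.stages, self.shortcuts):
            y = x
            for blk in stage:
                y = blk(y)
            x = (y + sc(x)).relu()
        return global_avg_pool(x)


class _RecurrentEncoder(Module):
    def __init__(self, rng, c_in: int, family: str, attention: str, hidden: int = 64):
        super().__init__()
        self.rnn = (GRU if family == "gru" else LSTM)(rng, c_in, hidden)
        self.attention = attention
        if attention == "single":
            self.att = AdditiveAttention(rng, hidden)
            self.latent_dim = hidden
        elif attention == "multihead":
            self.att = MultiHeadAttention(rng, hidden, heads=4)
            self.latent_dim = 4 * hidden
        else:
            self.att = None
            self.latent_dim = hidden

    def forward(self, x):
        outs, last = self.rnn(x)
        return self.att(outs) if self.att is not None else last


class _TCNEncoder(Module):
    """Dilated causal conv stack (dilations 1/2/4/8) with residual links."""

    def __init__(self, rng, c_in: int, width: int, attention: str):
        super().__init__()
        self.levels = []
        self.shortcuts = []
        c = c_in
        for d in (1, 2, 4, 8):
            self.levels.append(ConvBlock(rng, c, width, 3, dilation=d, padding="causal"))
            self.shortcuts.append(Conv1d(rng, c, width, 1) if c != width else None)
            c = width
        self.attention = attention
        self.att = SelfAttention(rng, width) if attention == "self" else None
        self.latent_dim = 32 if attention == "self" else width

    def forward(self, x):
        for lvl, sc in zip(self.levels, self.shortcuts):
            y = lvl(x)
            x = y + (sc(x) if sc is not None else x)
        if self.att is not None:
            return self.att(x.transpose((0, 2, 1)))
        return global_avg_pool(x)


def _make_encoder(rng, spec: ModelSpec, c_in: int) -> Module:
    f = spec.family
    if f == "cnn1d":
        return _ConvEncoder(rng, c_in, (16, 32), (7, 5))
    if f == "tiny_fcn":
        return _ConvEncoder(rng, c_in, (32, 64, 32), (8, 5, 3))
    if f == "inception_lite":
        return _InceptionEncoder(rng, c_in, 2, 8, None, residual=False)
    if f == "inception_time_small":
        return _InceptionEncoder(rng, c_in, 3, 8, 8, residual=True)
    if f == "resnet_tsc":
        return _ResNetEncoder(rng, c_in)
    if f in _RNN_FAMILIES:
        return _RecurrentEncoder(rng, c_in, f, spec.attention)
    if f in _TCN_FAMILIES:
        return _TCNEncoder(rng, c_in, 32 if f == "tcn" else 16, spec.attention)
    raise ValueError(f)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

class SingleViewClassifier(Module):
    def __init__(self, rng, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        self.encoder = _make_encoder(rng, spec, spec.in_channels)
        self.dropout = Dropout(spec.dropout, rng) if spec.dropout else None
        self.head = Linear(rng, self.encoder.latent_dim, spec.n_classes)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        z = self.encoder(x)
        if self.dropout is not None:
            z = self.dropout(z)
        return self.head(z)


class DualEncoderClassifier(Module):
    """Late fusion: independent trip/turn encoders, latents merged pre-head.

    ``concat`` fusion feeds the stacked latents to the head; ``gated`` fusion
    learns a sigmoid gate g from both latents and classifies
    g * z_trip + (1 - g) * z_turn.
    """

    def __init__(self, rng, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        self.trip_encoder = _make_encoder(rng, spec, spec.in_channels)
        self.turn_encoder = _make_encoder(rng, spec, spec.in_channels)
        d = self.trip_encoder.latent_dim
        if spec.fusion == "concat":
            head_in = 2 * d
            self.gate = None
        else:
            self.gate = Linear(rng, 2 * d, d)
            head_in = d
        self.dropout = Dropout(spec.dropout, rng) if spec.dropout else None
        self.head = Linear(rng, head_in, spec.n_classes)

    def forward(self, pair) -> Tensor:
        x_trip, x_turn = pair
        if not isinstance(x_trip, Tensor):
            x_trip = Tensor(x_trip)
        if not isinstance(x_turn, Tensor):
            x_turn = Tensor(x_turn)
        z1 = self.trip_encoder(x_trip)
        z2 = self.turn_encoder(x_turn)
        both = concat([z1, z2], axis=1)
        if self.gate is None:
            z = both
        else:
            g = self.gate(both).sigmoid()
            z = g * z1 + (1.0 - g) * z2
        if self.dropout is not None:
            z = self.dropout(z)
        return self.head(z)


def build_model(spec: ModelSpec, seed: int = 0) -> Module:
    """Instantiate a classifier with seeded, deterministic initialization."""
    rng = np.random.default_rng(seed)
    return DualEncoderClassifier(rng, spec) if spec.dual else SingleViewClassifier(rng, spec)


def predict_proba(model: Module, x, batch_size: int = 64) -> np.ndarray:
    """Class probabilities (rows sum to 1) in evaluation mode."""
    was_training = model.training
    model.eval()
    try:
        if isinstance(x, tuple):
            n = x[0].shape[0]
            batches = [(x[0][i:i + batch_size], x[1][i:i + batch_size])
                       for i in range(0, n, batch_size)]
        else:
            x = np.asarray(x)
            n = x.shape[0]
            batches = [x[i:i + batch_size] for i in range(0, n, batch_size)]
        if n == 0:
            return np.zeros((0, model.spec.n_classes))
        out = [softmax_probs(model(b).data) for b in batches]
    finally:
        if was_training:
            model.train()
    return np.concatenate(out, axis=0).astype(np.float64)


def spec_from_name(name: str, **overrides) -> ModelSpec:
    """Parse Table-style model names like 'DualGRU Attn' or 'TinyFCN'."""
    s = name.lower().replace("-", " ").replace("_", " ")
    dual = "dual" in s
    attention = "none"
    if "multihead" in s or "multiattention" in s or "multi" in s:
        attention = "multihead"
    elif "self" in s:
        attention = "self"
    elif "attn" in s or "attention" in s:
        attention = "single"
    family = None
    for cand, fam in [
        ("inceptiontimesmall", "inception_time_small"),
        ("inception time small", "inception_time_small"),
        ("inception lite", "inception_lite"),
        ("inceptionlite", "inception_lite"),
        ("resnet", "resnet_tsc"),
        ("tiny fcn", "tiny_fcn"), ("tinyfcn", "tiny_fcn"),
        ("tiny tcn", "tiny_tcn"), ("tinytcn", "tiny_tcn"),
        ("tcn", "tcn"), ("gru", "gru"), ("lstm", "lstm"),
        ("1d cnn", "cnn1d"), ("cnn", "cnn1d"),
    ]:
        if cand in s:
            family = fam
            break
    if family is None:
        raise ValueError(f"cannot parse model name {name!r}")
    if attention in ("single", "multihead") and family in _TCN_FAMILIES:
        attention = "self"
    spec = ModelSpec(family=family, dual=dual, attention=attention)
    return replace(spec, **overrides) if overrides else spec
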