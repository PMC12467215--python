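"""The lead-temporal co-attention network.

Input is a 4-axis map (batch N, channels C, leads l, time T).  A (3, 15)
stem convolution mixes neighbouring leads with a long time window; two
lead-temporal co-attention residual (LTCAR) blocks deepen the
representation; three parallel branches with temporal kernel widths 5, 7
and 15 capture short-, medium- and long-range context; their concatenation
is pooled globally and classified by a small MLP head.

Each LTCAR block is a pre-activation residual unit with two parallel paths:

* Path 1 (lead path): a (k, n) convolution spanning k neighbouring leads,
  gated by *spatial* attention - per-position sigmoid weights over the
  lead x time plane derived from channel-wise max and mean maps through a
  single 7x7 convolution - followed by whole-channel (feature-map) dropout.
* Path 2 (temporal path): a stack of m (1, n) convolutions confined to a
  single lead, gated by *channel* attention - squeeze-and-excitation
  weights from global average pooling through a bottleneck of reduction r.

The two paths are summed and added to the identity skip (1x1-projected
when channel counts change).  All convolutions are stride-1 and
same-padded; there is no spatial downsampling before the global pooling.

Every attention gate, the residual wiring, the number of branches, and the
whole block (plain convolution instead of LTCAR) can be switched off
independently for ablation studies.  ``swap_attention`` exchanges which
operator sits on which path, for the alternative reading of the two
mechanisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat
from .layers import (BatchNorm1d, BatchNorm2d, Conv2d, Dropout, Dropout2d,
                     Linear, Module)

__all__ = [
    "ModelConfig", "ChannelAttention", "SpatialAttention", "LTCARBlock",
    "MultiScaleBranches", "ClassifierHead", "CoAttentionECGNet",
    "build_model", "count_params",
]


@dataclass
class ModelConfig:
    """Every architectural hyperparameter, including ablation switches."""

    n_leads: int = 12
    input_len: int = 1000
    n_classes: int = 5
    stem_channels: int = 64
    ltcar1_channels: int = 128
    ltcar2_channels: int = 256
    branch_channels: int = 320
    branch_widths: list[int] = field(default_factory=lambda: [5, 7, 15])
    m_stack: int = 2            # stacked (1, n) convolutions on the temporal path
    k_lead: int = 3             # lead-kernel height in the stem-side blocks
    reduction_r: int = 16       # channel-attention bottleneck reduction
    dropout_p: float = 0.3
    spatial_kernel: int = 7     # spatial-attention convolution size
    use_lead_attention: bool = True
    use_temporal_attention: bool = True
    use_ltcar: bool = True      # False: plain conv stacks instead of LTCAR
    swap_attention: bool = False
    n_branches: int = 3         # 3, or 1 for the middle branch only
    head_hidden: int = 1024

    def __post_init__(self):
        if any(w % 2 == 0 for w in self.branch_widths):
            raise ValueError("branch widths must be odd")
        if self.n_branches not in (1, 3):
            raise ValueError("n_branches must be 1 or 3")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")

    def active_widths(self) -> list[int]:
        if self.n_branches == 3:
            return list(self.branch_widths)
        return [self.branch_widths[len(self.branch_widths) // 2]]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class ChannelAttention(Module):
    """Squeeze-and-excitation gate: GAP -> bottleneck MLP -> sigmoid scale."""

    def __init__(self, channels: int, reduction: int):
        super().__init__()
        hidden = max(math.ceil(channels / reduction), 1)
        self.fc1 = Linear(channels, hidden)
        self.fc2 = Linear(hidden, channels)

    def weights(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3))                      # (N, C)
        return self.fc2(self.fc1(s).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        return x * self.weights(x).reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """Per-position gate over the lead x time plane.

    Channel-wise max and mean maps are stacked as two channels and passed
    through a single same-padded convolution, then a sigmoid.
    """

    def __init__(self, kernel: int = 7):
        super().__init__()
        self.conv = Conv2d(2, 1, (kernel, kernel))

    def weights(self, x: Tensor) -> Tensor:
        mx = x.max(axis=1, keepdims=True)
        av = x.mean(axis=1, keepdims=True)
        return self.conv(concat([mx, av], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.weights(x)


class LTCARBlock(Module):
    """Lead-temporal co-attention residual block (pre-activation)."""

    def __init__(self, in_channels: int, out_channels: int, k: int, n: int,
                 cfg: ModelConfig):
        super().__init__()
        self.pre_bn = BatchNorm2d(in_channels)
        # path 1: lead path
        self.p1_conv = Conv2d(in_channels, out_channels, (k, n))
        self.p1_attn = None
        if cfg.use_lead_attention:
            self.p1_attn = (ChannelAttention(out_channels, cfg.reduction_r)
                            if cfg.swap_attention
                            else SpatialAttention(cfg.spatial_kernel))
        self.p1_drop = Dropout2d(cfg.dropout_p)
        # path 2: temporal path, m stacked (1, n) convolutions
        convs, bns = [], []
        ch = in_channels
        for _ in range(max(cfg.m_stack, 1)):
            convs.append(Conv2d(ch, out_channels, (1, n)))
            bns.append(BatchNorm2d(out_channels))
            ch = out_channels
        self.p2_convs = convs
        self.p2_bns = bns
        self.p2_attn = None
        if cfg.use_temporal_attention:
            self.p2_attn = (SpatialAttention(cfg.spatial_kernel)
                            if cfg.swap_attention
                            else ChannelAttention(out_channels, cfg.reduction_r))
        self.skip = (Conv2d(in_channels, out_channels, (1, 1))
                     if in_channels != out_channels else None)

    def forward(self, x: Tensor) -> Tensor:
        z = self.pre_bn(x).relu()
        p1 = self.p1_conv(z)
        if self.p1_attn is not None:
            p1 = self.p1_attn(p1)
        p1 = self.p1_drop(p1)
        p2 = z
        for conv, bn in zip(self.p2_convs, self.p2_bns):
            p2 = bn(conv(p2)).relu()
        if self.p2_attn is not None:
            p2 = self.p2_attn(p2)
        identity = x if self.skip is None else self.skip(x)
        return p1 + p2 + identity


class PlainConvBlock(Module):
    """Ablation stand-in for LTCAR: pre-activation convolution only."""

    def __init__(self, in_channels: int, out_channels: int, k: int, n: int,
                 cfg: ModelConfig):
        super().__init__()
        self.pre_bn = BatchNorm2d(in_channels)
        self.conv = Conv2d(in_channels, out_channels, (k, n))

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(self.pre_bn(x).relu())


def _block(cfg: ModelConfig, in_ch: int, out_ch: int, k: int, n: int) -> Module:
    cls = LTCARBlock if cfg.use_ltcar else PlainConvBlock
    return cls(in_ch, out_ch, k, n, cfg)


class Stem(Module):
    """Initialization layer: (3, 15) convolution, BN, ReLU, dropout."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        if cfg.input_len < 15:
            raise ValueError("input_len must be at least 15 samples")
        self.conv = Conv2d(1, cfg.stem_channels, (3, 15))
        self.bn = BatchNorm2d(cfg.stem_channels)
        self.drop = Dropout(cfg.dropout_p)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.bn(self.conv(x)).relu())


class Branch(Module):
    """One scale: LTCAR(3, n) -> 1x1 conv -> LTCAR(1, n)."""

    def __init__(self, cfg: ModelConfig, in_ch: int, n: int):
        super().__init__()
        bc = cfg.branch_channels
        self.block_a = _block(cfg, in_ch, bc, 3, n)
        self.mid_conv = Conv2d(bc, bc, (1, 1))
        self.mid_bn = BatchNorm2d(bc)
        self.block_b = _block(cfg, bc, bc, 1, n)
        self.width = n

    def forward(self, x: Tensor) -> Tensor:
        y = self.block_a(x)
        y = self.mid_bn(self.mid_conv(y)).relu()
        return self.block_b(y)


class MultiScaleBranches(Module):
    """Parallel branches concatenated along the channel axis."""

    def __init__(self, cfg: ModelConfig, in_ch: int):
        super().__init__()
        self.branches = [Branch(cfg, in_ch, n) for n in cfg.active_widths()]
        self.out_channels = cfg.branch_channels * len(self.branches)

    def forward(self, x: Tensor) -> Tensor:
        return concat([b(x) for b in self.branches], axis=1)


class ClassifierHead(Module):
    """GAP -> Linear -> BN -> GELU -> Dropout -> Linear (raw logits)."""

    def __init__(self, cfg: ModelConfig, in_ch: int):
        super().__init__()
        self.fc1 = Linear(in_ch, cfg.head_hidden)
        self.bn = BatchNorm1d(cfg.head_hidden)
        self.drop = Dropout(cfg.dropout_p)
        self.fc2 = Linear(cfg.head_hidden, cfg.n_classes)

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))              # (N, C)
        h = self.drop(self.bn(self.fc1(pooled)).gelu())
        return self.fc2(h)


class CoAttentionECGNet(Module):
    """Full network: stem -> 2 LTCAR blocks -> multi-scale branches -> head.

    ``forward(..., capture=True)`` records the named intermediate feature
    maps in ``self.activations`` for class-activation mapping.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.stem = Stem(cfg)
        self.ltcar1 = _block(cfg, cfg.stem_channels, cfg.ltcar1_channels,
                             cfg.k_lead, 15)
        self.ltcar2 = _block(cfg, cfg.ltcar1_channels, cfg.ltcar2_channels,
                             cfg.k_lead, 15)
        self.branches = MultiScaleBranches(cfg, cfg.ltcar2_channels)
        self.head = ClassifierHead(cfg, self.branches.out_channels)
        self.activations: dict[str, Tensor] = {}

    def layer_names(self) -> list[str]:
        return ["stem", "ltcar1", "ltcar2", "branch_concat"]

    def forward(self, x, capture: bool = False) -> Tensor:
        cfg = self.cfg
        data = x.data if isinstance(x, Tensor) else np.asarray(x)
        if data.ndim != 4:
            raise ValueError(f"expected 4 axes (N, C, leads, time), got {data.ndim}")
        if data.shape[1] != 1:
            raise ValueError(f"channel axis must be 1 at input, got {data.shape[1]}")
        if data.shape[2] != cfg.n_leads:
            raise ValueError(f"lead axis is {data.shape[2]}, expected {cfg.n_leads}")
        if data.shape[3] != cfg.input_len:
            raise ValueError(f"time axis is {data.shape[3]}, expected {cfg.input_len}")
        x = Tensor(np.ascontiguousarray(data, dtype=np.float32))
        if capture:
            x.requires_grad = True
            x.retain_grad = True
        acts: dict[str, Tensor] = {}
        h = self.stem(x)
        acts["stem"] = h
        h = self.ltcar1(h)
        acts["ltcar1"] = h
        h = self.ltcar2(h)
        acts["ltcar2"] = h
        h = self.branches(h)
        acts["branch_concat"] = h
        if capture:
            for t in acts.values():
                t.requires_grad = True
                t.retain_grad = True
            self.activations = acts
        return self.head(h)


def build_model(cfg: ModelConfig) -> CoAttentionECGNet:
    return CoAttentionECGNet(cfg)


def count_params(cfg: ModelConfig) -> int:
    """Total trainable scalar parameter count for a configuration."""
    return build_model(cfg).count_params()
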