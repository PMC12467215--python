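"""Neural-network building blocks on top of :mod:`ecgcoattn.autodiff`.

Layers follow the usual Module convention: submodules and parameters are
discovered by attribute walking, ``train()`` / ``eval()`` toggle batch-norm
statistics and dropout, and an :class:`AdamW` optimizer updates parameters
with decoupled weight decay.

Convolutions are stride-1 with symmetric "same" zero padding on both the
lead and the time axis, which is the only variant the architecture uses
(there is no spatial downsampling before global average pooling).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._conv_kernels import conv_forward, conv_grad_weight
from .autodiff import DTYPE, Tensor

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "Linear",
    "BatchNorm2d", "BatchNorm1d", "Dropout", "Dropout2d", "AdamW",
]


class Parameter(Tensor):
    """Trainable tensor; ``decay=False`` opts out of weight decay."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.decay = decay


class Module:
    def __init__(self):
        self.training = True

    # -- discovery ---------------------------------------------------------
    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for c in self.children():
            yield from c.modules()

    def parameters(self) -> Iterator[Parameter]:
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    yield v

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    # -- mode --------------------------------------------------------------
    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, (BatchNorm2d, BatchNorm1d)):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=DTYPE).copy()
        for name, m in self._named_modules():
            if isinstance(m, (BatchNorm2d, BatchNorm1d)):
                m.running_mean = np.asarray(state[f"{name}.running_mean"],
                                            dtype=DTYPE).copy()
                m.running_var = np.asarray(state[f"{name}.running_var"],
                                           dtype=DTYPE).copy()

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Module):
                yield full, v
                yield from v._named_modules(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{full}.{i}", item
                        yield from item._named_modules(f"{full}.{i}.")

    def set_dropout_rng(self, rng: np.random.Generator):
        for m in self.modules():
            if isinstance(m, (Dropout, Dropout2d)):
                m.rng = rng
        return self

    def count_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    """Stride-1, same-padded 2-D convolution over (lead, time) maps.

    Feature maps are channels-first: (batch, channels, leads, time); the
    weight is stored (out_channels, in_channels, kh, kw).  Kernel sizes
    must be odd on both axes so symmetric padding preserves the spatial
    extent exactly.  The arithmetic runs in compiled row-vectorized
    kernels (see ``_conv_kernels``).
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int], bias: bool = True):
        super().__init__()
        kh, kw = kernel_size
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError(f"kernel sizes must be odd, got {kernel_size}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = (kh, kw)
        fan_in = in_channels * kh * kw
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(
            np.random.default_rng(0).uniform(-bound, bound,
                                             (out_channels, in_channels, kh, kw)))
        self.bias = Parameter(np.zeros(out_channels), decay=False) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        kh, kw = self.kernel_size
        ph, pw = kh // 2, kw // 2
        w = self.weight
        b = self.bias
        N, C, H, W = x.data.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        co = self.out_channels
        ap = np.ascontiguousarray(
            np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))))
        bias_arr = b.data if b is not None else np.zeros(co, dtype=DTYPE)
        out_data = np.empty((N, co, H, W), dtype=DTYPE)
        conv_forward(ap, w.data, bias_arr, out_data)
        req = x.requires_grad or w.requires_grad
        parents = (x, w) if b is None else (x, w, b)
        out = Tensor(out_data, req, parents)

        def bw(g):
            g = np.ascontiguousarray(g)
            if b is not None:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                apb = np.ascontiguousarray(
                    np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))))
                dw = np.zeros_like(w.data)
                conv_grad_weight(apb, g, dw)
                w._accumulate(dw)
            if x.requires_grad:
                # transposed convolution: correlate the padded upstream
                # gradient with the flipped, channel-transposed kernel
                gp = np.ascontiguousarray(
                    np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw))))
                wt = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
                dx = np.empty((N, C, H, W), dtype=DTYPE)
                conv_forward(gp, wt, np.zeros(C, dtype=DTYPE), dx)
                x._accumulate(dx)

        out._backward = bw
        return out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            np.random.default_rng(0).uniform(-bound, bound,
                                             (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features), decay=False) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x.matmul(self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class _BatchNormBase(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features), decay=False)
        self.beta = Parameter(np.zeros(num_features), decay=False)
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def _normalize(self, x: Tensor, axes: tuple[int, ...], shape) -> Tensor:
        gamma, beta = self.gamma, self.beta
        xd = x.data
        if self.training:
            mu = xd.mean(axis=axes, keepdims=True)
            var = xd.var(axis=axes, keepdims=True)
            m = xd.size // self.num_features
            self.running_mean += self.momentum * (mu.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.reshape(-1) * m / max(m - 1, 1) - self.running_var)
        else:
            mu = self.running_mean.reshape(shape)
            var = self.running_var.reshape(shape)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        mu = np.asarray(mu, dtype=DTYPE)
        xhat = (xd - mu) * inv
        out_data = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
        out = Tensor(out_data, x.requires_grad or gamma.requires_grad,
                     (x, gamma, beta))
        del xhat     # recomputed cheaply in backward; mu/inv are tiny
        training = self.training

        def bw(g):
            xhat_b = (x.data - mu) * inv
            if gamma.requires_grad:
                gamma._accumulate((g * xhat_b).sum(axis=axes))
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                dxhat = g * gamma.data.reshape(shape)
                if training:
                    dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
                          - xhat_b * (dxhat * xhat_b).mean(axis=axes,
                                                           keepdims=True)) * inv
                else:
                    dx = dxhat * inv
                x._accumulate(dx.astype(DTYPE))

        out._backward = bw
        return out


class BatchNorm2d(_BatchNormBase):
    """Per-channel statistics over (batch, leads, time)."""

    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (0, 2, 3), (1, self.num_features, 1, 1))


class BatchNorm1d(_BatchNormBase):
    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (0,), (1, self.num_features))


class Dropout(Module):
    """Elementwise inverted dropout; identity in eval mode or at p = 0."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng: np.random.Generator = np.random.default_rng(0)

    def _mask_shape(self, x: Tensor):
        return x.data.shape

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(self._mask_shape(x)) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class Dropout2d(Dropout):
    """Whole-channel (feature-map) dropout: zeroes entire (lead, time) maps."""

    def _mask_shape(self, x: Tensor):
        n, c = x.data.shape[:2]
        return (n, c, 1, 1)


class AdamW(Module):
    """Adam with decoupled weight decay; learning rate may vary per step."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        super().__init__()
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            if self.weight_decay and getattr(p, "decay", True):
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
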