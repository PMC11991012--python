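"""Layers, parameter containers and the SGD optimizer built on autodiff.

Modules follow the familiar container pattern: parameters are discovered by
walking attributes, ``state_dict``/``load_state_dict`` move plain numpy
arrays, and initialization is driven by an explicit ``numpy.random.Generator``
so every network build is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, unfold2d, unfold2d_out_hw

__all__ = ["Parameter", "Module", "Linear", "Conv2d", "max_pool2x2",
           "avg_pool2x2", "masked_softmax", "softmax", "SGD"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base container: tracks Parameters and sub-Modules by attribute name."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, weight_scale: float | None = None,
                 bias_init: float = 0.0):
        scale = weight_scale if weight_scale is not None else np.sqrt(
            1.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale,
                                           (out_features, in_features)))
        self.bias = Parameter(np.full(out_features, bias_init))

    def forward(self, x: Tensor) -> Tensor:
        # x: (..., in_features)
        return x @ self.weight.T + self.bias


class Conv2d(Module):
    """2D convolution on (C,H,W) tensors via im2col."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (out_channels, fan_in)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[0] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, "
                             f"got {x.shape[0]}")
        ho, wo = unfold2d_out_hw(x.shape, self.kernel, self.stride,
                                 self.padding)
        cols = unfold2d(x, self.kernel, self.stride, self.padding)
        out = self.weight @ cols + self.bias.reshape(self.out_channels, 1)
        return out.reshape(self.out_channels, ho, wo)


def _pool2x2(x: Tensor, mode: str) -> Tensor:
    C, H, W = x.shape
    ho, wo = unfold2d_out_hw(x.shape, 2, 2, 0)
    cols = unfold2d(x, 2, stride=2, padding=0).reshape(C, 4, ho * wo)
    red = cols.max(axis=1) if mode == "max" else cols.mean(axis=1)
    return red.reshape(C, ho, wo)


def max_pool2x2(x: Tensor) -> Tensor:
    return _pool2x2(x, "max")


def avg_pool2x2(x: Tensor) -> Tensor:
    return _pool2x2(x, "avg")


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax(x: Tensor, keep: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over the entries where ``keep`` is True; zeros elsewhere.

    ``keep`` is a constant boolean mask (no gradient flows through it); every
    slice along ``axis`` must retain at least one entry.
    """
    if not keep.any(axis=axis).all():
        raise ValueError("masked_softmax: a slice has no surviving entries")
    keep_f = keep.astype(np.float64)
    # shift by each slice's own surviving maximum: every slice then has a
    # unit term, so the normalizer never underflows
    masked = np.where(keep, x.data, -np.inf)
    big = masked.max(axis=axis, keepdims=True)
    shifted = x - Tensor(np.broadcast_to(big, x.data.shape).copy())
    # zero out discarded entries *before* the exp so they can neither
    # overflow nor receive gradient
    gate = Tensor(keep_f)
    e = (shifted * gate).exp() * gate
    return e / e.sum(axis=axis, keepdims=True)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0, clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            sq = sum(float((p.grad ** 2).sum()) for p in self.params
                     if p.grad is not None)
            total = np.sqrt(sq)
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"velocity": [v.copy() for v in self.velocity]}

    def load_state_dict(self, state: dict) -> None:
        vel = state["velocity"]
        if len(vel) != len(self.velocity):
            raise ValueError("optimizer state size mismatch")
        self.velocity = [np.asarray(v, dtype=np.float64).copy() for v in vel]
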