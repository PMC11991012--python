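"""Weight-shared feature encoder.

One encoder object serves both the support and the query branch of an
episode — parameter sharing is structural, not a training-time constraint.
The default backbone is a three-block strided CNN (overall stride 8) sized
for desk-scale experiments; the backbone is pluggable so a heavier network
(e.g. a pretrained residual net tapped at 1/8 resolution) can be dropped in
behind the same ``encode`` contract.

The final convolution carries no activation, so features span negative
values and cosine similarity to a prototype can use its full [-1, 1] range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .errors import ShapeMismatch
from .nn import Conv2d, Module

__all__ = ["EncoderConfig", "TinyCNNEncoder", "build_encoder",
           "load_nifti_slices"]


@dataclass
class EncoderConfig:
    backbone: str = "tiny"
    out_channels: int = 64
    stride: int = 8          # image-to-feature downsampling factor
    in_size: int = 64        # expected square input size
    pretrained: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.stride < 1 or self.in_size % self.stride:
            raise ValueError("output stride must be >= 1 and divide the "
                             "input size")


class TinyCNNEncoder(Module):
    """Three strided 3x3 conv blocks; overall stride 8.

    Input: (3,H,W) channel-replicated intensity image.  Output:
    (C, H/8, W/8) feature map.
    """

    def __init__(self, cfg: EncoderConfig):
        if cfg.stride != 8:
            raise ValueError("TinyCNNEncoder is a stride-8 backbone")
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        c = cfg.out_channels
        self.conv1 = Conv2d(3, c // 4, 3, rng, stride=2, padding=1)
        self.conv2 = Conv2d(c // 4, c // 2, 3, rng, stride=2, padding=1)
        self.conv3 = Conv2d(c // 2, c, 3, rng, stride=2, padding=1)

    def forward(self, image) -> Tensor:
        x = image if isinstance(image, Tensor) else Tensor(image)
        if x.ndim != 3 or x.shape[0] != 3:
            raise ShapeMismatch(f"expected (3,H,W) image, got {x.shape}")
        if x.shape[1] != self.cfg.in_size or x.shape[2] != self.cfg.in_size:
            raise ShapeMismatch(
                f"expected {self.cfg.in_size}x{self.cfg.in_size} input, "
                f"got {x.shape[1]}x{x.shape[2]}")
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        return self.conv3(x)

    encode = Module.__call__


_BACKBONES = {"tiny": TinyCNNEncoder}


def build_encoder(cfg: EncoderConfig) -> Module:
    try:
        cls = _BACKBONES[cfg.backbone]
    except KeyError:
        raise ValueError(f"unknown backbone {cfg.backbone!r}; "
                         f"registered: {sorted(_BACKBONES)}") from None
    return cls(cfg)


def register_backbone(name: str, factory) -> None:
    """Register an encoder backbone factory taking an EncoderConfig."""
    _BACKBONES[name] = factory


def to_image_slice(gray: np.ndarray) -> np.ndarray:
    """Min-max normalize a 2D slice to [0,1] and replicate to 3 channels."""
    gray = np.asarray(gray, dtype=np.float64)
    lo, hi = gray.min(), gray.max()
    if hi > lo:
        gray = (gray - lo) / (hi - lo)
    else:
        gray = np.zeros_like(gray)
    return np.repeat(gray[None], 3, axis=0)


def load_nifti_slices(path: str, axis: int = 2):
    """Yield channel-replicated, [0,1]-normalized 2D slices of a NIfTI volume.

    Requires nibabel (optional dependency); slice axis configurable.
    """
    import nibabel as nib  # deferred: optional dependency

    vol = np.asanyarray(nib.load(path).dataobj).astype(np.float64)
    vol = np.moveaxis(vol, axis, 0)
    for sl in vol:
        yield to_image_slice(sl)
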