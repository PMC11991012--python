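"""Onion pooling: nested mask erosion, per-layer prototypes, self-attention.

The support mask is peeled layer by layer with an *erosion pooling* (EP)
step — invert the mask, 2x2 max-pool the background, invert back — which is
exactly morphological erosion of the foreground by a 2x2 structuring element
anchored at the top-left, with out-of-bounds treated as background and the
spatial size preserved (stride-1 pooling, so every onion mask can still be
pooled against the same feature grid).

Each layer yields one masked-average prototype; the resulting prototype set
is then mixed by a single-head self-attention so the nested prototypes
learn from one another before refinement and aggregation.

Layer 1 is the un-eroded support mask by default (``include_base_layer``),
so even a single-pixel organ contributes one prototype; erosion stops
before an empty layer or at ``n_max`` layers (default 4).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, stack
from .errors import EmptyMask
from .nn import Module, softmax
from .protomath import masked_average_pool

__all__ = ["erode_mask", "build_onion_masks", "extract_prototypes",
           "mix_prototypes", "PrototypeMixer", "OnionPooling"]

DEFAULT_N_MAX = 4


def erode_mask(mask: np.ndarray) -> np.ndarray:
    """One EP step: 2x2 erosion of the foreground, top-left anchor.

    Pixel (i,j) stays foreground iff all of {(i,j), (i,j+1), (i+1,j),
    (i+1,j+1)} are foreground; out-of-bounds counts as background.  Same
    output size; may return an all-zero mask.
    """
    m = np.asarray(mask) > 0.5
    H, W = m.shape
    padded = np.zeros((H + 1, W + 1), dtype=bool)
    padded[:H, :W] = m
    out = (padded[:H, :W] & padded[:H, 1:W + 1]
           & padded[1:H + 1, :W] & padded[1:H + 1, 1:W + 1])
    return out.astype(np.float64)


def build_onion_masks(support_mask: np.ndarray,
                      n_max: int = DEFAULT_N_MAX,
                      include_base_layer: bool = True) -> list[np.ndarray]:
    """Nested onion-mask stack, largest first.

    Layer 1 is the input mask (if ``include_base_layer``) or its first
    erosion; each next layer is the erosion of the previous one.  Stops
    before adding an empty layer or upon reaching ``n_max`` layers.
    """
    m = np.asarray(support_mask, dtype=np.float64)
    if m.sum() < 0.5:
        raise EmptyMask("support mask has no foreground")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    current = (m > 0.5).astype(np.float64)
    if not include_base_layer:
        current = erode_mask(current)
        if current.sum() < 0.5:
            raise EmptyMask("support mask vanished after one erosion")
    layers = [current]
    while len(layers) < n_max:
        nxt = erode_mask(layers[-1])
        if nxt.sum() < 0.5:
            break
        layers.append(nxt)
    return layers


def extract_prototypes(features: Tensor, layers: list[np.ndarray]
                       ) -> list[Tensor]:
    """Masked-average prototype per onion layer (layers are nonempty)."""
    return [masked_average_pool(features, layer) for layer in layers]


class PrototypeMixer(Module):
    """Single-head self-attention over the prototype set (token = prototype)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        from .dfca import ProjectionWeights
        self.proj = ProjectionWeights(channels, rng)
        self.channels = channels

    def forward(self, prototypes: list[Tensor]) -> list[Tensor]:
        return mix_prototypes(prototypes, self.proj)


def mix_prototypes(prototypes: list[Tensor], proj) -> list[Tensor]:
    """Scaled dot-product self-attention mixing; count preserved.

    With a single prototype the softmax is a singleton, so the output is
    just its value projection.  There is no positional encoding, so the
    mixing is equivariant under permutation of the input order.
    """
    if not prototypes:
        raise EmptyMask("prototype set is empty")
    X = stack(prototypes, axis=0)              # (n, C)
    Q, K, V = proj.q(X), proj.k(X), proj.v(X)
    dk = float(proj.channels)
    attn = softmax((Q @ K.T) * (1.0 / np.sqrt(dk)), axis=1)
    mixed = attn @ V
    return [mixed[i] for i in range(len(prototypes))]


class OnionPooling(Module):
    """Erode -> pool -> mix, as one module."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 n_max: int = DEFAULT_N_MAX, include_base_layer: bool = True):
        self.mixer = PrototypeMixer(channels, rng)
        self.n_max = n_max
        self.include_base_layer = include_base_layer

    def forward(self, features: Tensor, support_mask: np.ndarray
                ) -> list[Tensor]:
        layers = build_onion_masks(support_mask, self.n_max,
                                   self.include_base_layer)
        protos = extract_prototypes(features, layers)
        return self.mixer(protos)
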