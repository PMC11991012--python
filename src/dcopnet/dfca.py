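"""Dual-filter cross attention (DFCA).

Three blocks executed in sequence:

1. **Prior mask generation (PMG)** — pool a prior support prototype by MAP,
   score the query features against it, and soft-threshold at the prior
   threshold ``Ta`` to get a prior query foreground mask.
2. **Feature fusion** — concatenate each branch's features with the tiled
   prior prototype and that branch's mask, and project back to C channels
   with a 1x1 convolution, pulling support and query into a shared space.
3. **Filter cross attention (FCA)** — mask-gate each branch (first filter),
   run cross attention between the two foreground fields with an adaptive
   score filter ``V_filter = (max + mean) / 2`` (second filter), and restore
   the background of the enhanced branch from its fused features.

The attention query is always projected from the branch being enhanced and
keys/values from the other branch, so the output stays spatially aligned
with the enhanced branch.  Attention is single-head; tokens are all pixels
of the feature grid, masked by Hadamard product rather than index dropping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .errors import ShapeMismatch
from .nn import Conv2d, Linear, Module, masked_softmax
from .protomath import (DEFAULT_ALPHA, DEFAULT_STEEPNESS, anomaly_score_map,
                        masked_average_pool, soft_threshold_mask)

__all__ = ["FilteredScores", "ProjectionWeights", "FusionConv",
           "generate_prior_mask", "fuse_features", "filter_scores",
           "fca_enhance", "DFCAModule"]

DEFAULT_PRIOR_THRESHOLD = -10.0


@dataclass
class FilteredScores:
    """Raw attention scores plus the boolean survivor mask of the filter."""
    scores: Tensor            # (Nq_tokens, Nk_tokens), scaled by 1/sqrt(dk)
    keep: np.ndarray          # same shape, True where the entry survives
    v_filter: float


class ProjectionWeights(Module):
    """Q/K/V linear projections for one attention direction."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.q = Linear(channels, channels, rng)
        self.k = Linear(channels, channels, rng)
        self.v = Linear(channels, channels, rng)
        self.channels = channels


class FusionConv(Module):
    """1x1 projection of [features ; tiled prototype ; mask] back to C."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv = Conv2d(2 * channels + 1, channels, 1, rng)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


def generate_prior_mask(support_feats: Tensor, support_mask, query_feats: Tensor,
                        alpha: float = DEFAULT_ALPHA,
                        prior_threshold: float = DEFAULT_PRIOR_THRESHOLD,
                        steepness: float = DEFAULT_STEEPNESS):
    """PMG: prior support prototype and prior query foreground mask.

    ``support_mask`` must already be at feature resolution.  Returns
    ``(prototype, prior_mask)``; raises :class:`EmptyMask` via MAP when the
    support mask is empty.
    """
    prototype = masked_average_pool(support_feats, support_mask)
    scores = anomaly_score_map(query_feats, prototype, alpha)
    prior = soft_threshold_mask(scores, prior_threshold, steepness)
    return prototype, prior


def tile_prototype(prototype: Tensor, hw: tuple) -> Tensor:
    """Broadcast a length-C prototype to a (C,H,W) prototype map."""
    ones = Tensor(np.ones((1, hw[0], hw[1])))
    return prototype.reshape(-1, 1, 1) * ones


def fuse_features(features: Tensor, prototype: Tensor, mask,
                  fusion: FusionConv) -> Tensor:
    """Eq-style feature fusion: concat [F ; tile(p) ; M], 1x1-project to C."""
    mask = mask if isinstance(mask, Tensor) else Tensor(mask)
    if features.shape[1:] != mask.shape:
        raise ShapeMismatch(f"features {features.shape} vs mask {mask.shape}")
    pmap = tile_prototype(prototype, features.shape[1:])
    stacked = concat([features, pmap, mask.reshape(1, *mask.shape)], axis=0)
    return fusion(stacked)


def filter_scores(raw: Tensor, allowed_cols: np.ndarray | None = None
                  ) -> FilteredScores:
    """Adaptive second filter on an attention score matrix.

    Entries strictly above ``V_filter = (max + mean) / 2`` survive
    (``V_filter`` is global over the matrix).  Columns excluded up front
    (e.g. key tokens whose mask weight is exactly 0) never survive.  Any row
    left without a survivor falls back to retaining its maximal allowed
    entries, so the subsequent softmax is always well defined.
    """
    data = raw.data
    if allowed_cols is None:
        allowed_cols = np.ones(data.shape[1], dtype=bool)
    if not allowed_cols.any():
        raise ShapeMismatch("no attention key tokens available")
    allowed = np.broadcast_to(allowed_cols, data.shape)
    v_filter = (data.max() + data.mean()) / 2.0
    keep = (data > v_filter) & allowed
    # tie/degenerate fallback: keep each starved row's maximal allowed entries
    starved = ~keep.any(axis=1)
    if starved.any():
        masked = np.where(allowed, data, -np.inf)
        row_max = masked.max(axis=1, keepdims=True)
        fallback = (masked == row_max) & allowed
        keep[starved] = fallback[starved]
    return FilteredScores(scores=raw, keep=keep, v_filter=float(v_filter))


def _tokens(x: Tensor) -> Tensor:
    """(C,H,W) -> (H*W, C) token matrix."""
    C = x.shape[0]
    return x.reshape(C, -1).T


def _attend(q_src: Tensor, kv_src: Tensor, proj: ProjectionWeights,
            kv_mask_flat: np.ndarray) -> Tensor:
    """One filtered cross-attention direction on token matrices."""
    Q = proj.q(_tokens(q_src))
    K = proj.k(_tokens(kv_src))
    V = proj.v(_tokens(kv_src))
    dk = float(proj.channels)
    raw = (Q @ K.T) * (1.0 / np.sqrt(dk))
    filtered = filter_scores(raw, allowed_cols=kv_mask_flat > 0.0)
    attn = masked_softmax(filtered.scores, filtered.keep, axis=1)
    out = attn @ V
    C = q_src.shape[0]
    h, w = q_src.shape[1], q_src.shape[2]
    return out.T.reshape(C, h, w)


def fca_enhance(support_fused: Tensor, support_mask, query_fused: Tensor,
                query_prior_mask, w_support: ProjectionWeights,
                w_query: ProjectionWeights):
    """Filter cross attention producing enhanced support and query features.

    First filter: Hadamard-gate each branch by its mask.  Attention: Q from
    the branch being enhanced, K/V from the other branch; scores pass the
    adaptive value filter before the softmax.  Background restore:
    ``F_enh = M * attended + (1 - M) * F_fused``.
    """
    ms = support_mask if isinstance(support_mask, Tensor) else Tensor(support_mask)
    mq = query_prior_mask if isinstance(query_prior_mask, Tensor) \
        else Tensor(query_prior_mask)
    if support_fused.shape != query_fused.shape:
        raise ShapeMismatch("support/query feature shapes differ")
    if support_fused.shape[1:] != ms.shape or query_fused.shape[1:] != mq.shape:
        raise ShapeMismatch("mask resolution does not match features")

    s_fg = support_fused * ms.reshape(1, *ms.shape)
    q_fg = query_fused * mq.reshape(1, *mq.shape)

    attended_s = _attend(s_fg, q_fg, w_support, mq.data.reshape(-1))
    attended_q = _attend(q_fg, s_fg, w_query, ms.data.reshape(-1))

    ms3 = ms.reshape(1, *ms.shape)
    mq3 = mq.reshape(1, *mq.shape)
    support_enh = ms3 * attended_s + (1.0 - ms3) * support_fused
    query_enh = mq3 * attended_q + (1.0 - mq3) * query_fused
    return support_enh, query_enh


class DFCAModule(Module):
    """PMG -> feature fusion (shared 1x1 conv) -> filter cross attention."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 alpha: float = DEFAULT_ALPHA,
                 prior_threshold: float = DEFAULT_PRIOR_THRESHOLD,
                 steepness: float = DEFAULT_STEEPNESS):
        self.fusion = FusionConv(channels, rng)
        self.w_support = ProjectionWeights(channels, rng)
        self.w_query = ProjectionWeights(channels, rng)
        self.alpha = alpha
        self.prior_threshold = prior_threshold
        self.steepness = steepness

    def forward(self, support_feats: Tensor, support_mask,
                query_feats: Tensor):
        """Returns (support_enh, query_enh, query_prior_mask, prior_proto)."""
        prototype, prior = generate_prior_mask(
            support_feats, support_mask, query_feats,
            self.alpha, self.prior_threshold, self.steepness)
        s_fused = fuse_features(support_feats, prototype, support_mask,
                                self.fusion)
        q_fused = fuse_features(query_feats, prototype, prior, self.fusion)
        s_enh, q_enh = fca_enhance(s_fused, support_mask, q_fused, prior,
                                   self.w_support, self.w_query)
        return s_enh, q_enh, prior, prototype

    dfca_forward = Module.__call__
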