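"""Parallel threshold perception (PTP) and the anomaly-score segmentor.

PTP predicts one scalar anomaly-score threshold per episode from the raw
and enhanced query features: both are channel-concatenated, passed through
one shared 3x3 convolution, then split into a max-pool branch (salient
structure) and an avg-pool branch (overall intensity field).  The branch
outputs are concatenated, downsampled by conv/relu/max-pool blocks until
the grid is at most 4x4, flattened, and mapped to the scalar by a fully
connected layer.  The FC bias initializes at the prior threshold (-10), so
an untrained head starts from the fixed-threshold baseline scheme.

The segmentor scores every query pixel against the global prototype
(negative scaled cosine similarity) and soft-thresholds at the predicted
threshold, yielding the soft predicted query mask.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .errors import ShapeMismatch
from .nn import Conv2d, Linear, Module, avg_pool2x2, max_pool2x2
from .protomath import (DEFAULT_ALPHA, DEFAULT_STEEPNESS, anomaly_score_map,
                        soft_threshold_mask)

__all__ = ["PTPHead", "segment_query"]

DEFAULT_THRESHOLD_INIT = -10.0


class PTPHead(Module):
    """Dual-path threshold perception head for a fixed feature geometry."""

    def __init__(self, channels: int, feature_hw: tuple,
                 rng: np.random.Generator, mid_channels: int = 32,
                 threshold_init: float = DEFAULT_THRESHOLD_INIT):
        self.channels = channels
        self.feature_hw = tuple(feature_hw)
        # one convolution shared by both branches
        self.shared_conv = Conv2d(2 * channels, mid_channels, 3, rng,
                                  padding=1)
        h, w = feature_hw
        h, w = h // 2, w // 2          # branch 2x2 pooling, stride 2
        self.ds_blocks: list[Conv2d] = []
        c = 2 * mid_channels           # branches concatenated
        while max(h, w) > 4:
            self.ds_blocks.append(Conv2d(c, c, 3, rng, padding=1))
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ShapeMismatch(f"feature grid {feature_hw} too small for "
                                "the threshold head")
        # small FC weights + bias at the prior threshold: the head starts
        # out predicting the baseline fixed threshold
        self.fc = Linear(c * h * w, 1, rng, weight_scale=0.01,
                         bias_init=threshold_init)

    def forward(self, query_feats: Tensor, query_enh: Tensor) -> Tensor:
        if query_feats.shape != query_enh.shape:
            raise ShapeMismatch("raw and enhanced query features must share "
                                "a shape")
        if query_feats.shape[1:] != self.feature_hw:
            raise ShapeMismatch(
                f"head built for {self.feature_hw}, got "
                f"{query_feats.shape[1:]}")
        x = concat([query_feats, query_enh], axis=0)
        shared = self.shared_conv(x).relu()
        branches = concat([max_pool2x2(shared), avg_pool2x2(shared)], axis=0)
        for blk in self.ds_blocks:
            branches = max_pool2x2(blk(branches).relu())
        flat = branches.reshape(1, -1)
        return self.fc(flat).reshape(())

    ptp_threshold = Module.__call__


def segment_query(query_feats: Tensor, prototype: Tensor, threshold,
                  alpha: float = DEFAULT_ALPHA,
                  steepness: float = DEFAULT_STEEPNESS) -> Tensor:
    """Predicted soft query mask at feature resolution.

    ``M = 1 - sigmoid(k * (S - Tp))`` with ``S`` the anomaly-score map of
    the query features against the global prototype.  Raises
    :class:`DegeneratePrototype` for a zero-norm prototype.
    """
    scores = anomaly_score_map(query_feats, prototype, alpha)
    return soft_threshold_mask(scores, threshold, steepness)
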