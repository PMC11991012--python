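"""The four-term episodic training objective.

``L_total = L_s + L_q + L_par + L_qsr`` with

* ``L_s``  — binary cross-entropy of the predicted query mask vs. ground
  truth,
* ``L_q``  — the same cross-entropy on the prior-mask branch (the prior
  query mask upsampled to image resolution), supervising the PMG pathway,
* ``L_par`` — prototype-alignment regularization: the soft predicted query
  mask pools a query prototype that must segment the support image back
  (role swap),
* ``L_qsr`` — query self-reference: the predicted mask pools a query
  prototype that re-segments the query itself; scaled by a growth factor
  ``beta = 0.02 * (epoch + 1)`` so the feedback term strengthens as
  predictions become trustworthy.

All cross-entropies are nonnegative; soft predicted masks are used directly
as pooling weights (no binarization) so every term stays differentiable.
When the predicted mask is too empty to pool from — routine in the first
training iterations — the QSR/alignment terms contribute zero and a warning
is logged rather than aborting the step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .errors import ShapeMismatch
from .protomath import (CLIP_EPS, DEFAULT_ALPHA, DEFAULT_STEEPNESS, MASK_EPS,
                        anomaly_score_map, masked_average_pool,
                        soft_threshold_mask)

__all__ = ["LossBundle", "bce_mask_loss", "beta_schedule", "qsr_loss",
           "alignment_loss", "total_loss"]

logger = logging.getLogger(__name__)

BETA_STEP = 0.02


@dataclass
class LossBundle:
    total: Tensor          # differentiable scalar
    seg: float             # L_s
    query: float           # L_q
    align: float           # L_par
    qsr: float             # L_qsr
    beta: float
    epoch: int

    def as_dict(self) -> dict:
        return {"Ls": self.seg, "Lq": self.query, "Lpar": self.align,
                "Lqsr": self.qsr, "Ltotal": float(self.total.data),
                "beta": self.beta, "epoch": self.epoch}


def bce_mask_loss(pred, target) -> Tensor:
    """Mean binary cross-entropy between a soft mask and a hard target.

    Predictions are clipped to [eps, 1-eps] (eps = 1e-7) before the logs.
    """
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    tgt = np.asarray(target.data if isinstance(target, Tensor) else target,
                     dtype=np.float64)
    if pred.shape != tgt.shape:
        raise ShapeMismatch(f"pred {pred.shape} vs target {tgt.shape}")
    p = pred.clip(CLIP_EPS, 1.0 - CLIP_EPS)
    t = Tensor(tgt)
    ll = t * p.log() + (1.0 - t) * (1.0 - p).log()
    return -ll.mean()


def beta_schedule(epoch: int) -> float:
    """QSR growth factor: 0.02 at epoch 0, increasing by 0.02 per epoch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return BETA_STEP * (epoch + 1)


def _self_reference_mask(query_feats: Tensor, pooling_mask: Tensor,
                         threshold, alpha: float,
                         steepness: float) -> Tensor | None:
    """Pool a prototype from a predicted mask and re-segment; None if the
    predicted mask is too empty to pool from."""
    if float(pooling_mask.data.sum()) <= MASK_EPS:
        return None
    proto = masked_average_pool(query_feats, pooling_mask)
    scores = anomaly_score_map(query_feats, proto, alpha)
    return soft_threshold_mask(scores, threshold, steepness)


def qsr_loss(query_feats: Tensor, pred_mask: Tensor, query_mask, threshold,
             beta: float, alpha: float = DEFAULT_ALPHA,
             steepness: float = DEFAULT_STEEPNESS) -> Tensor:
    """Query self-reference regularization, scaled by the growth factor.

    The soft predicted query mask acts as a 'new support mask' over the
    query's own features; the re-segmentation is scored against ground
    truth.  Contributes 0 (with a warning) on an empty prediction.
    """
    resegmented = _self_reference_mask(query_feats, pred_mask, threshold,
                                       alpha, steepness)
    if resegmented is None:
        logger.warning("QSR skipped: predicted query mask is empty")
        return Tensor(0.0)
    return beta * bce_mask_loss(resegmented, query_mask)


def alignment_loss(support_feats: Tensor, support_mask, query_feats: Tensor,
                   pred_mask: Tensor, threshold,
                   alpha: float = DEFAULT_ALPHA,
                   steepness: float = DEFAULT_STEEPNESS) -> Tensor:
    """Prototype-alignment regularization (support/query role swap).

    A query prototype pooled under the predicted mask segments the support
    features; the result is scored against the support mask.  Contributes 0
    (with a warning) on an empty prediction.
    """
    if float(pred_mask.data.sum()) <= MASK_EPS:
        logger.warning("alignment loss skipped: predicted query mask is empty")
        return Tensor(0.0)
    proto = masked_average_pool(query_feats, pred_mask)
    scores = anomaly_score_map(support_feats, proto, alpha)
    resegmented = soft_threshold_mask(scores, threshold, steepness)
    return bce_mask_loss(resegmented, support_mask)


def total_loss(pred_mask_img: Tensor, prior_mask_img: Tensor,
               query_mask_img, support_mask_feat, support_feats: Tensor,
               query_feats: Tensor, pred_mask_feat: Tensor, threshold,
               epoch: int, alpha: float = DEFAULT_ALPHA,
               steepness: float = DEFAULT_STEEPNESS,
               use_qsr: bool = True, use_align: bool = True) -> LossBundle:
    """Assemble the four-term objective for one episode.

    Image-resolution masks feed the two supervised cross-entropies; the
    feature-resolution predicted mask drives the role-swap terms (pooling
    happens on the feature grid).
    """
    seg = bce_mask_loss(pred_mask_img, query_mask_img)
    query = bce_mask_loss(prior_mask_img, query_mask_img)
    beta = beta_schedule(epoch)
    if use_align:
        align = alignment_loss(support_feats, support_mask_feat, query_feats,
                               pred_mask_feat, threshold, alpha, steepness)
    else:
        align = Tensor(0.0)
    if use_qsr:
        # QSR compares against the query ground truth at feature resolution
        qmask_feat = _downsample_target(query_mask_img, query_feats.shape[1:])
        qsr = qsr_loss(query_feats, pred_mask_feat, qmask_feat, threshold,
                       beta, alpha, steepness)
    else:
        qsr = Tensor(0.0)
    total = seg + query + align + qsr
    return LossBundle(total=total, seg=float(seg.data),
                      query=float(query.data), align=float(align.data),
                      qsr=float(qsr.data), beta=beta, epoch=epoch)


def _downsample_target(mask, out_hw: tuple) -> np.ndarray:
    from .protomath import downsample_mask_nearest
    data = mask.data if isinstance(mask, Tensor) else np.asarray(mask)
    if data.shape == tuple(out_hw):
        return data
    return downsample_mask_nearest(data, out_hw)
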