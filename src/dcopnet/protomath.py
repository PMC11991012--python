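"""Differentiable prototype-segmentation primitives and the Dice metric.

The whole prototype pipeline reduces to four small operations:

* masked average pooling (MAP) — pool a class prototype ``p`` from a feature
  map under a (soft) foreground mask,
* anomaly scoring — per-pixel negative scaled cosine similarity
  ``S(h,w) = -alpha * cos(F(h,w), p)``, so foreground pixels score low,
* shifted-sigmoid soft thresholding — ``M = 1 - sigmoid(k * (S - T))``, a
  differentiable binarization around a threshold ``T``,
* the Dice overlap score, reported on the percentage scale.

All tensor-valued functions accept and return :class:`~dcopnet.autodiff.Tensor`
and are differentiable end-to-end; the mask resamplers at the bottom bridge
between image resolution (e.g. 256x256 ground truth) and the encoder's
feature grid.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .errors import DegeneratePrototype, EmptyMask, ShapeMismatch

# sum-of-mask tolerance below which a mask counts as empty
MASK_EPS = 1e-5
# clamp for feature/prototype norms in the cosine denominator; keeps
# backprop defined on dead (all-zero) activations
NORM_EPS = 1e-8
# probability clip before logarithms in cross-entropies
CLIP_EPS = 1e-7

DEFAULT_ALPHA = 20.0
DEFAULT_STEEPNESS = 0.5


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def masked_average_pool(features: Tensor, mask) -> Tensor:
    """Pool a length-C prototype from (C,H,W) features under an (H,W) mask.

    ``p_c = sum_hw F_c(h,w) M(h,w) / sum_hw M(h,w)``.  The mask may be soft;
    raises :class:`EmptyMask` when its total weight is below ``MASK_EPS``.
    """
    features = _lift(features)
    mask = _lift(mask)
    if features.ndim != 3 or mask.ndim != 2:
        raise ShapeMismatch("expected (C,H,W) features and (H,W) mask")
    if features.shape[1:] != mask.shape:
        raise ShapeMismatch(f"features {features.shape} vs mask {mask.shape}")
    total = float(mask.data.sum())
    if total <= MASK_EPS:
        raise EmptyMask(f"mask weight {total} <= {MASK_EPS}")
    weighted = features * mask.reshape(1, *mask.shape)
    return weighted.sum(axis=(1, 2)) / mask.sum()


def anomaly_score_map(features: Tensor, prototype: Tensor,
                      alpha: float = DEFAULT_ALPHA) -> Tensor:
    """Negative scaled cosine similarity of every pixel to the prototype.

    Returns an (H,W) map with values in [-alpha, +alpha]; pixels whose
    feature points along the prototype score -alpha (strong foreground
    evidence).  Zero-norm pixels are handled by clamping the denominator.
    """
    features = _lift(features)
    prototype = _lift(prototype)
    if features.shape[0] != prototype.shape[0]:
        raise ShapeMismatch("channel count of features and prototype differ")
    pnorm = float(np.linalg.norm(prototype.data))
    if pnorm <= NORM_EPS:
        raise DegeneratePrototype(f"prototype norm {pnorm} <= {NORM_EPS}")
    dot = (features * prototype.reshape(-1, 1, 1)).sum(axis=0)
    fnorm = ((features ** 2.0).sum(axis=0) + NORM_EPS ** 2) ** 0.5
    pn = (prototype ** 2.0).sum() ** 0.5
    return dot / (fnorm * pn) * (-alpha)


def soft_threshold_mask(scores: Tensor, threshold,
                        steepness: float = DEFAULT_STEEPNESS) -> Tensor:
    """Differentiable thresholding: ``1 - sigmoid(k * (S - T))``.

    Scores below ``T`` map above 0.5 (foreground); strictly decreasing in S
    and saturating at {0,1}.  ``threshold`` may be a scalar or a 0-d Tensor
    (the learned threshold stays trainable through this op).
    """
    scores = _lift(scores)
    threshold = _lift(threshold)
    return 1.0 - ((scores - threshold) * steepness).sigmoid()


def binarize(mask, level: float = 0.5) -> np.ndarray:
    """Hard {0,1} mask from a soft mask (numpy out; not differentiable)."""
    data = mask.data if isinstance(mask, Tensor) else np.asarray(mask)
    return (data > level).astype(np.float64)


def dice_score(a, b) -> float:
    """Dice overlap of two binary masks on the percentage scale.

    ``D = 2|A n B| / (|A| + |B|) * 100``; two empty masks agree perfectly
    and score 100.
    """
    a = np.asarray(a.data if isinstance(a, Tensor) else a) > 0.5
    b = np.asarray(b.data if isinstance(b, Tensor) else b) > 0.5
    if a.shape != b.shape:
        raise ShapeMismatch(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 100.0
    return float(2.0 * np.logical_and(a, b).sum() / denom * 100.0)


# --------------------------------------------------------------- resampling
def downsample_mask_nearest(mask: np.ndarray, out_hw: tuple) -> np.ndarray:
    """Nearest-neighbor resample of a hard mask to the feature grid."""
    mask = np.asarray(mask, dtype=np.float64)
    H, W = mask.shape
    ho, wo = out_hw
    rows = np.clip(((np.arange(ho) + 0.5) * H / ho - 0.5).round(), 0,
                   H - 1).astype(int)
    cols = np.clip(((np.arange(wo) + 0.5) * W / wo - 0.5).round(), 0,
                   W - 1).astype(int)
    return mask[np.ix_(rows, cols)]


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1D bilinear interpolation matrix (n_out, n_in)."""
    A = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    A[np.arange(n_out), lo] += 1.0 - frac
    A[np.arange(n_out), hi] += frac
    return A


def upsample_bilinear(mask: Tensor, out_hw: tuple) -> Tensor:
    """Differentiable bilinear resize of an (H,W) soft mask."""
    mask = _lift(mask)
    A = Tensor(_interp_matrix(mask.shape[0], out_hw[0]))
    B = Tensor(_interp_matrix(mask.shape[1], out_hw[1]))
    return A @ mask @ B.T
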