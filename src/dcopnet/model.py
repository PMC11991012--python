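"""End-to-end network: encoder -> DFCA -> onion pooling -> refinement ->
threshold perception -> segmentor.

``DCOPNet.forward`` consumes one 1-way episode (support image+mask, query
image) and returns every intermediate the losses and evaluation need.  The
module toggles mirror the ablation grid:

* ``use_dfca=False`` — skip feature fusion/cross attention (the prior mask
  is still generated, since the query-branch loss supervises it),
* ``use_op=False``   — a single masked-average prototype instead of the
  onion stack and mixer,
* ``use_ptp=False``  — replace the perception head by one learnable scalar
  threshold (the fixed-threshold baseline scheme),
* ``use_qsr=False``  — drop the self-reference loss term (handled by the
  training loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .dfca import DFCAModule, DEFAULT_PRIOR_THRESHOLD
from .encoder import EncoderConfig, build_encoder
from .errors import ShapeMismatch
from .nn import Module, Parameter
from .onion_pool import DEFAULT_N_MAX, OnionPooling, build_onion_masks
from .proto_refine import (ProtoRefiner, RefinerConfig, aggregate_global,
                           refine_prototypes)
from .protomath import (DEFAULT_ALPHA, DEFAULT_STEEPNESS,
                        downsample_mask_nearest, masked_average_pool,
                        upsample_bilinear)
from .seg_head import PTPHead, segment_query

__all__ = ["ModelConfig", "DCOPNet", "EpisodeOutput"]


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    refiner: RefinerConfig = field(default_factory=RefinerConfig)
    alpha: float = DEFAULT_ALPHA
    prior_threshold: float = DEFAULT_PRIOR_THRESHOLD   # Ta
    steepness: float = DEFAULT_STEEPNESS               # k
    n_max: int = DEFAULT_N_MAX
    include_base_layer: bool = True
    use_dfca: bool = True
    use_op: bool = True
    use_ptp: bool = True
    use_qsr: bool = True
    seed: int = 0


@dataclass
class EpisodeOutput:
    pred_mask_feat: Tensor      # soft predicted query mask, feature grid
    pred_mask_img: Tensor       # bilinearly upsampled to image grid
    prior_mask_feat: Tensor     # prior query mask, feature grid
    prior_mask_img: Tensor
    threshold: Tensor           # Tp (0-d)
    prototype: Tensor           # global segmentation prototype
    support_feats: Tensor       # raw encoder output, support branch
    query_feats: Tensor         # raw encoder output, query branch
    support_mask_feat: np.ndarray
    n_onion_layers: int


class DCOPNet(Module):
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = build_encoder(cfg.encoder)
        c = cfg.encoder.out_channels
        fh = cfg.encoder.in_size // cfg.encoder.stride
        self.feature_hw = (fh, fh)
        self.dfca = DFCAModule(c, rng, cfg.alpha, cfg.prior_threshold,
                               cfg.steepness)
        self.onion = OnionPooling(c, rng, cfg.n_max, cfg.include_base_layer)
        self.refiner = ProtoRefiner(c, cfg.refiner)
        self.ptp = PTPHead(c, self.feature_hw, rng)
        # baseline scheme: one directly learnable scalar threshold
        self.fixed_threshold = Parameter(np.asarray(cfg.prior_threshold))

    def forward(self, support_img, support_mask, query_img) -> EpisodeOutput:
        cfg = self.cfg
        support_img = np.asarray(support_img, dtype=np.float64)
        query_img = np.asarray(query_img, dtype=np.float64)
        support_mask = np.asarray(support_mask, dtype=np.float64)
        if support_mask.shape != support_img.shape[1:]:
            raise ShapeMismatch("support mask must match image resolution")

        fs = self.encoder(support_img)
        fq = self.encoder(query_img)
        ms_feat = downsample_mask_nearest(support_mask, self.feature_hw)

        if cfg.use_dfca:
            fs_enh, fq_enh, prior, _ = self.dfca(fs, ms_feat, fq)
        else:
            from .dfca import generate_prior_mask
            _, prior = generate_prior_mask(fs, ms_feat, fq, cfg.alpha,
                                           cfg.prior_threshold, cfg.steepness)
            fs_enh, fq_enh = fs, fq

        if cfg.use_op:
            layers = build_onion_masks(ms_feat, cfg.n_max,
                                       cfg.include_base_layer)
            from .onion_pool import extract_prototypes
            protos = self.onion.mixer(extract_prototypes(fs_enh, layers))
        else:
            layers = [ms_feat]
            protos = [masked_average_pool(fs_enh, ms_feat)]

        protos = refine_prototypes(protos, fq, prior, self.refiner)
        prototype = aggregate_global(protos)

        if cfg.use_ptp:
            threshold = self.ptp(fq, fq_enh)
        else:
            threshold = self.fixed_threshold

        pred_feat = segment_query(fq, prototype, threshold, cfg.alpha,
                                  cfg.steepness)
        img_hw = support_img.shape[1:]
        # image-resolution predictions interpolate the anomaly-score field
        # and threshold at full resolution: the score is the natural
        # continuous quantity, and interpolating after the saturating
        # sigmoid would smear the boundary
        from .protomath import anomaly_score_map, soft_threshold_mask
        pred_scores = anomaly_score_map(fq, prototype, cfg.alpha)
        pred_img = soft_threshold_mask(
            upsample_bilinear(pred_scores, img_hw), threshold, cfg.steepness)
        prior_proto_scores = anomaly_score_map(
            fq, masked_average_pool(fs, ms_feat), cfg.alpha)
        prior_img = soft_threshold_mask(
            upsample_bilinear(prior_proto_scores, img_hw),
            cfg.prior_threshold, cfg.steepness)
        return EpisodeOutput(
            pred_mask_feat=pred_feat,
            pred_mask_img=pred_img,
            prior_mask_feat=prior,
            prior_mask_img=prior_img,
            threshold=threshold,
            prototype=prototype,
            support_feats=fs,
            query_feats=fq,
            support_mask_feat=ms_feat,
            n_onion_layers=len(layers),
        )
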