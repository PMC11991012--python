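"""Prototype refinement and global aggregation.

After onion pooling, the prototype set is refined against the query features
and collapsed into a single segmentation prototype by global average
pooling.  The refinement stage is deliberately pluggable: strategies are
registered callables honoring ``(prototypes, query_feats, query_prior_mask,
cfg) -> prototypes``.

Two strategies ship with the library:

* ``"identity"`` — pass the prototypes through unchanged;
* ``"query_cross_attention"`` (default) — pool a coarse query prototype by
  MAP under the prior query mask and add a residual, learned-projection
  attention step ``P_j <- P_j + gamma * Attn(P_j -> {p_q})`` to every
  support prototype.

The cross-attention default is intentionally simple; heavier refinement
transformers can be plugged in through the registry without touching the
rest of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack
from .errors import EmptyMask, UnknownStrategy
from .nn import Linear, Module
from .protomath import masked_average_pool

__all__ = ["RefinerConfig", "QueryCrossAttentionRefiner", "ProtoRefiner",
           "refine_prototypes", "aggregate_global", "register_strategy"]


@dataclass
class RefinerConfig:
    strategy: str = "query_cross_attention"
    residual_weight: float = 0.5   # gamma in [0, 1]
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.residual_weight <= 1.0:
            raise ValueError("residual_weight must lie in [0, 1]")


class QueryCrossAttentionRefiner(Module):
    """Residual cross attention from each prototype to the coarse query
    prototype (a single key/value token, so the attention weight is 1 and
    the learned value projection carries the refinement)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 gamma: float = 0.5):
        # with a singleton key set the softmax weight is identically 1, so
        # only the value projection is learnable; q/k projections would be
        # dead weights and are omitted
        self.v = Linear(channels, channels, rng)
        self.gamma = gamma

    def forward(self, prototypes: list[Tensor], query_feats: Tensor,
                query_prior_mask) -> list[Tensor]:
        if self.gamma == 0.0:
            return list(prototypes)
        mask_data = query_prior_mask.data if isinstance(
            query_prior_mask, Tensor) else np.asarray(query_prior_mask)
        # a (near-)empty prior mask gives no usable coarse query prototype,
        # and its pooled gradient (~1/sum^2) would explode: pass through
        if float(mask_data.sum()) <= 1e-3:
            return list(prototypes)
        coarse = masked_average_pool(query_feats, query_prior_mask)
        delta = self.v(coarse)
        return [p + self.gamma * delta for p in prototypes]


def _identity(prototypes, query_feats, query_prior_mask, module):
    return list(prototypes)


def _query_cross_attention(prototypes, query_feats, query_prior_mask, module):
    return module(prototypes, query_feats, query_prior_mask)


_STRATEGIES = {
    "identity": _identity,
    "query_cross_attention": _query_cross_attention,
}


def register_strategy(name: str, fn) -> None:
    """Register a refinement strategy callable.

    Signature: ``fn(prototypes, query_feats, query_prior_mask, module) ->
    list of prototypes`` with count preserved.
    """
    _STRATEGIES[name] = fn


class ProtoRefiner(Module):
    """Strategy dispatcher owning the learnable refinement weights."""

    def __init__(self, channels: int, cfg: RefinerConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        if cfg.strategy not in _STRATEGIES:
            raise UnknownStrategy(
                f"{cfg.strategy!r}; registered: {sorted(_STRATEGIES)}")
        self.attn = QueryCrossAttentionRefiner(channels, rng,
                                               cfg.residual_weight)

    def forward(self, prototypes: list[Tensor], query_feats: Tensor,
                query_prior_mask) -> list[Tensor]:
        if not prototypes:
            raise EmptyMask("prototype set is empty")
        fn = _STRATEGIES.get(self.cfg.strategy)
        if fn is None:
            raise UnknownStrategy(self.cfg.strategy)
        out = fn(prototypes, query_feats, query_prior_mask, self.attn)
        if len(out) != len(prototypes):
            raise ValueError("refinement strategy must preserve the "
                             "prototype count")
        return out


def refine_prototypes(prototypes: list[Tensor], query_feats: Tensor,
                      query_prior_mask, refiner: ProtoRefiner) -> list[Tensor]:
    return refiner(prototypes, query_feats, query_prior_mask)


def aggregate_global(prototypes: list[Tensor]) -> Tensor:
    """Global average pooling of the prototype set into one prototype.

    The forward value is computed with exactly rounded summation (fsum), so
    it is bit-identical under any permutation of the inputs; the gradient
    of a mean is uniform, so backward needs no ordering either.
    """
    if not prototypes:
        raise EmptyMask("cannot aggregate an empty prototype set")
    n = len(prototypes)
    val = np.array([math.fsum(vals) / n
                    for vals in zip(*(p.data for p in prototypes))])
    out = Tensor(val, _parents=tuple(prototypes))

    def bw(g):
        for p in prototypes:
            p._accum(g / n)
    out._backward = bw if out.requires_grad else None
    return out
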