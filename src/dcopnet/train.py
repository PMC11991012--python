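"""Episodic training loop, checkpointing, and the evaluation harness.

Per iteration: sample an episode, run the full forward pass, assemble the
four-term loss, backpropagate, and take an SGD step.  The learning rate
decays exponentially per epoch (``lr0 * decay^epoch``); batch size is one
episode.  Checkpoints carry model weights, optimizer momentum, the episode
sampler's bit-generator state and the iteration count, so an interrupted
run resumes to bit-identical results.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .encoder import EncoderConfig
from .errors import CheckpointError, ConfigError
from .losses import total_loss
from .model import DCOPNet, ModelConfig
from .nn import SGD
from .proto_refine import RefinerConfig
from .protomath import binarize, dice_score
from .synth import DEFAULT_CLASSES, ClassSpec, episode_stream

__all__ = ["TrainConfig", "EvalReport", "train", "evaluate",
           "save_checkpoint", "load_checkpoint", "build_model"]

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    iterations: int = 15000
    iterations_per_epoch: int = 5000
    learning_rate: float = 0.001
    decay_rate: float = 0.98          # per-epoch exponential lr decay
    batch_size: int = 1
    momentum: float = 0.9
    weight_decay: float = 0.0
    clip_norm: float | None = 5.0     # global gradient-norm clip
    model: ModelConfig = field(default_factory=ModelConfig)
    data_seed: int = 0
    setting: int = 2
    heldout: str | None = None
    image_size: int = 64
    log_path: str | None = None       # JSONL metrics log

    def __post_init__(self):
        if self.iterations < 1 or self.iterations_per_epoch < 1:
            raise ConfigError("iteration counts must be positive")
        if self.batch_size != 1:
            raise ConfigError("only batch size 1 is supported")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        model_raw = raw.pop("model", {})
        enc_raw = model_raw.pop("encoder", {})
        ref_raw = model_raw.pop("refiner", {})
        model = ModelConfig(encoder=EncoderConfig(**enc_raw),
                            refiner=RefinerConfig(**ref_raw), **model_raw)
        return cls(model=model, **raw)


@dataclass
class EvalReport:
    mean_dice: float
    per_episode: list
    n_episodes: int
    seed: int


def build_model(cfg: TrainConfig) -> DCOPNet:
    if cfg.model.encoder.in_size != cfg.image_size:
        raise ConfigError("encoder in_size must equal the episode image size")
    return DCOPNet(cfg.model)


def _lr_at(cfg: TrainConfig, iteration: int) -> float:
    epoch = iteration // cfg.iterations_per_epoch
    return cfg.learning_rate * cfg.decay_rate ** epoch


def train(cfg: TrainConfig, model: DCOPNet | None = None,
          episodes=None, start_iteration: int = 0,
          optimizer: SGD | None = None, log_sink=None) -> dict:
    """Run (or continue) an episodic training loop.

    ``episodes``: iterator of Episodes; defaults to a synthetic stream from
    the built-in classes.  Returns a dict with the model, optimizer, final
    loss and the loss history.
    """
    if model is None:
        model = build_model(cfg)
    if episodes is None:
        episodes = episode_stream(DEFAULT_CLASSES, split_seed=cfg.data_seed,
                                  setting=cfg.setting, heldout=cfg.heldout,
                                  size=cfg.image_size)
    if optimizer is None:
        optimizer = SGD(model.parameters(), lr=cfg.learning_rate,
                        momentum=cfg.momentum,
                        weight_decay=cfg.weight_decay,
                        clip_norm=cfg.clip_norm)
    history = []
    log_file = open(log_sink, "a") if isinstance(log_sink, (str, Path)) \
        else None
    try:
        for it in range(start_iteration, start_iteration + cfg.iterations):
            episode = next(episodes)
            epoch = it // cfg.iterations_per_epoch
            optimizer.lr = _lr_at(cfg, it)

            out = model(episode.support_images[0], episode.support_masks[0],
                        episode.query_images[0])
            bundle = total_loss(
                pred_mask_img=out.pred_mask_img,
                prior_mask_img=out.prior_mask_img,
                query_mask_img=episode.query_masks[0],
                support_mask_feat=out.support_mask_feat,
                support_feats=out.support_feats,
                query_feats=out.query_feats,
                pred_mask_feat=out.pred_mask_feat,
                threshold=out.threshold,
                epoch=epoch,
                alpha=cfg.model.alpha,
                steepness=cfg.model.steepness,
                use_qsr=cfg.model.use_qsr,
            )
            optimizer.zero_grad()
            bundle.total.backward()
            optimizer.step()

            record = bundle.as_dict()
            record.update(iteration=it, lr=optimizer.lr,
                          Tp=float(out.threshold.data),
                          episode_seed=episode.seed)
            history.append(record)
            if log_file is not None:
                log_file.write(json.dumps(record) + "\n")
    finally:
        if log_file is not None:
            log_file.close()
    return {"model": model, "optimizer": optimizer,
            "final_loss": history[-1]["Ltotal"] if history else None,
            "history": history,
            "iteration": start_iteration + cfg.iterations}


def evaluate(model: DCOPNet, episodes, n_episodes: int,
             seed: int = 0) -> EvalReport:
    """Mean Dice (%) of binarized, upsampled predictions over episodes."""
    scores = []
    for _ in range(n_episodes):
        episode = next(episodes)
        out = model(episode.support_images[0], episode.support_masks[0],
                    episode.query_images[0])
        pred = binarize(out.pred_mask_img)
        scores.append(dice_score(pred, episode.query_masks[0]))
    return EvalReport(mean_dice=float(np.mean(scores)), per_episode=scores,
                      n_episodes=n_episodes, seed=seed)


def predict(model: DCOPNet, support_img, support_mask, query_img):
    """Single-episode inference: (soft mask, binary mask) at image size."""
    out = model(support_img, support_mask, query_img)
    soft = out.pred_mask_img.data
    return soft, binarize(soft)


# --------------------------------------------------------------- checkpoints
def save_checkpoint(path, model: DCOPNet, cfg: TrainConfig,
                    iteration: int, optimizer: SGD | None = None,
                    sampler_state=None) -> None:
    payload = {
        "version": CHECKPOINT_VERSION,
        "state": model.state_dict(),
        "config": asdict(cfg),
        "iteration": iteration,
        "optimizer": optimizer.state_dict() if optimizer else None,
        "sampler_state": sampler_state,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path):
    """Returns (model, TrainConfig, payload dict)."""
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (OSError, pickle.UnpicklingError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if payload.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(f"unsupported checkpoint version "
                              f"{payload.get('version')}")
    raw = payload["config"]
    model_raw = dict(raw.pop("model"))
    model_cfg = ModelConfig(
        encoder=EncoderConfig(**model_raw.pop("encoder")),
        refiner=RefinerConfig(**model_raw.pop("refiner")), **model_raw)
    cfg = TrainConfig(model=model_cfg, **raw)
    model = build_model(cfg)
    try:
        model.load_state_dict(payload["state"])
    except (KeyError, ValueError) as exc:
        raise CheckpointError(f"incompatible checkpoint: {exc}") from exc
    return model, cfg, payload
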