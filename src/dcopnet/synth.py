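"""Synthetic organ-like episodes for building and testing the pipeline.

Each class is a distribution over smooth blob shapes (an ellipse whose
radius is perturbed by low-frequency radial noise) with a characteristic
size range and intensity offset against a smoothly textured background,
plus additive Gaussian noise.  Support and query images of an episode are
independent draws from the same class-conditional distribution, which is
what a prototype-based few-shot segmenter exploits: shape statistics and
contrast are shared, exact geometry is not.

Two evaluation protocols are emulated for held-out-class experiments:
*setting 1* allows the held-out class to appear as an unlabeled background
distractor in training images; *setting 2* guarantees it never appears
anywhere in the training stream.

Everything is driven by explicit seeds: the same (spec, seed) pair
reproduces an episode bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DcopError

__all__ = ["ClassSpec", "Episode", "make_episode", "episode_stream",
           "write_episode_dir", "DEFAULT_CLASSES"]


class DegenerateShape(DcopError):
    """A sampled organ was too small even after retries."""


@dataclass(frozen=True)
class ClassSpec:
    """Shape/intensity statistics of one synthetic organ class."""
    name: str = "organ"
    shape: str = "blob"                      # "ellipse" | "blob"
    size_range: tuple = (0.05, 0.15)         # foreground area fraction
    intensity_range: tuple = (0.35, 0.55)    # organ brightness offset
    noise_sd: float = 0.05
    boundary_wobble: float = 0.15            # radial perturbation amplitude
    eccentricity: float = 0.35               # max |1 - axis ratio|

    def __post_init__(self):
        lo, hi = self.size_range
        if not (0.005 < lo <= hi < 0.5):
            raise ConfigError("size_range must lie within (0.005, 0.5)")
        if self.shape not in ("ellipse", "blob"):
            raise ConfigError(f"unknown shape family {self.shape!r}")


@dataclass
class Episode:
    """One 1-way K-shot task: K support pairs and Nq query pairs."""
    support_images: list   # each (3,H,W) float64 in [0,1]
    support_masks: list    # each (H,W) float64 in {0,1}
    query_images: list
    query_masks: list
    class_name: str
    seed: int


_MIN_AREA_PX = 4
_RETRY_CAP = 50


def _sample_shape(rng: np.random.Generator, spec: ClassSpec,
                  size: int) -> np.ndarray:
    """Rasterize one organ-like binary mask."""
    frac = rng.uniform(*spec.size_range)
    r0 = np.sqrt(frac * size * size / np.pi)
    margin = max(int(np.ceil(r0 * (1 + spec.boundary_wobble))), 2)
    margin = min(margin, size // 2 - 1)
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    ecc = rng.uniform(-spec.eccentricity, spec.eccentricity)
    ry, rx = r0 * (1 + ecc), r0 / (1 + ecc)
    theta0 = rng.uniform(0, 2 * np.pi)

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = (yy - cy) / ry, (xx - cx) / rx
    rr = np.sqrt(dy ** 2 + dx ** 2)
    if spec.shape == "blob":
        ang = np.arctan2(dy, dx)
        wobble = np.zeros_like(rr)
        for m in (2, 3, 4):
            amp = rng.uniform(0, spec.boundary_wobble / 2)
            phase = rng.uniform(0, 2 * np.pi)
            wobble += amp * np.cos(m * (ang + theta0) + phase)
        rr = rr / (1.0 + wobble)
    return (rr <= 1.0).astype(np.float64)


def _background(rng: np.random.Generator, size: int) -> np.ndarray:
    """Smooth low-frequency background texture around intensity 0.25."""
    noise = rng.normal(0.0, 1.0, (size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=size / 8)
    smooth /= max(np.abs(smooth).max(), 1e-9)
    return 0.25 + 0.08 * smooth


def _feature_grid_hit(mask: np.ndarray, stride: int = 8) -> bool:
    """Does a nearest-neighbor stride-8 downsampling see the organ?"""
    from .protomath import downsample_mask_nearest
    h, w = mask.shape
    if h < stride or w < stride:
        return mask.sum() > 0
    return downsample_mask_nearest(mask, (h // stride, w // stride)).sum() > 0


def _render_pair(rng: np.random.Generator, spec: ClassSpec, size: int,
                 distractor_specs: list) -> tuple:
    """One (image, mask) draw; distractor organs never enter the mask."""
    for _ in range(_RETRY_CAP):
        mask = _sample_shape(rng, spec, size)
        if mask.sum() >= _MIN_AREA_PX and _feature_grid_hit(mask):
            break
    else:
        raise DegenerateShape(f"class {spec.name!r}: organ below "
                              f"{_MIN_AREA_PX} px after {_RETRY_CAP} retries")
    img = _background(rng, size)
    for dspec in distractor_specs:
        dmask = _sample_shape(rng, dspec, size)
        dmask *= 1.0 - mask          # the labeled organ stays on top
        img = img + dmask * rng.uniform(*dspec.intensity_range)
    img = img + mask * rng.uniform(*spec.intensity_range)
    img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return np.repeat(img[None], 3, axis=0), mask


def make_episode(spec: ClassSpec, k: int = 1, nq: int = 1, size: int = 64,
                 seed: int = 0, distractor_specs: list | None = None
                 ) -> Episode:
    """Sample one 1-way K-shot episode; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    distractor_specs = list(distractor_specs or [])
    sup_i, sup_m, qry_i, qry_m = [], [], [], []
    for _ in range(k):
        img, mask = _render_pair(rng, spec, size, distractor_specs)
        sup_i.append(img)
        sup_m.append(mask)
    for _ in range(nq):
        img, mask = _render_pair(rng, spec, size, distractor_specs)
        qry_i.append(img)
        qry_m.append(mask)
    return Episode(sup_i, sup_m, qry_i, qry_m, spec.name, seed)


DEFAULT_CLASSES = {
    "A": ClassSpec(name="A", shape="blob", size_range=(0.06, 0.14),
                   intensity_range=(0.40, 0.55)),
    "B": ClassSpec(name="B", shape="ellipse", size_range=(0.08, 0.18),
                   intensity_range=(0.35, 0.50)),
    "C": ClassSpec(name="C", shape="blob", size_range=(0.05, 0.10),
                   intensity_range=(0.45, 0.60)),
}


def episode_stream(class_specs: dict, split_seed: int = 0, setting: int = 2,
                   heldout: str | None = None, k: int = 1, nq: int = 1,
                   size: int = 64, distractor_prob: float = 0.5):
    """Infinite iterator of training episodes over the non-held-out classes.

    Setting 2 guarantees the held-out class appears nowhere in the stream;
    setting 1 lets it show up as a background distractor with probability
    ``distractor_prob``.  Equal split seeds give identical streams.
    """
    if setting not in (1, 2):
        raise ConfigError("setting must be 1 or 2")
    train_names = [n for n in sorted(class_specs) if n != heldout]
    if not train_names:
        raise ConfigError("no training classes left after holding out")
    if setting == 2 and heldout is not None and len(class_specs) < 2:
        raise ConfigError("setting-2 hold-out requires at least two classes")
    rng = np.random.default_rng(split_seed)
    while True:
        name = train_names[rng.integers(len(train_names))]
        distractors = []
        if rng.random() < distractor_prob:
            if setting == 1 and heldout is not None:
                pool = [n for n in sorted(class_specs) if n != name]
            else:
                pool = [n for n in train_names if n != name]
            if pool:
                distractors = [class_specs[pool[rng.integers(len(pool))]]]
        yield make_episode(class_specs[name], k=k, nq=nq, size=size,
                           seed=int(rng.integers(2 ** 31)),
                           distractor_specs=distractors)


# ------------------------------------------------------------------ fixtures
def write_episode_dir(episode: Episode, out_dir) -> Path:
    """Dump an episode as PNG images + masks with a JSON manifest."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def save_img(arr, path):
        Image.fromarray(
            (np.clip(arr, 0, 1) * 255).astype(np.uint8)).save(path)

    manifest = {"class": episode.class_name, "seed": episode.seed,
                "support": [], "query": []}
    for i, (img, mask) in enumerate(zip(episode.support_images,
                                        episode.support_masks)):
        ip, mp = f"support_{i}_img.png", f"support_{i}_mask.png"
        save_img(img[0], out / ip)
        save_img(mask, out / mp)
        manifest["support"].append({"image": ip, "mask": mp})
    for i, (img, mask) in enumerate(zip(episode.query_images,
                                        episode.query_masks)):
        ip, mp = f"query_{i}_img.png", f"query_{i}_mask.png"
        save_img(img[0], out / ip)
        save_img(mask, out / mp)
        manifest["query"].append({"image": ip, "mask": mp})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_image(path) -> np.ndarray:
    """Load a grayscale PNG as a (3,H,W) channel-replicated [0,1] image."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0
    return np.repeat(arr[None], 3, axis=0)


def read_mask(path) -> np.ndarray:
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0
    return (arr > 0.5).astype(np.float64)
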