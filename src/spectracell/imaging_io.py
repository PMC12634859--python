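"""Image-folder loading, augmentation, and channel normalization.

Datasets follow the class-per-subdirectory layout (one folder per class,
JPEG/PNG inside). Augmentation — flips, rotation, color jitter, random
affine, cutout — is applied only to the training portion; validation and
test images are strictly resized and normalized. All randomness flows
through an explicit ``numpy.random.Generator`` so augmentation streams are
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["LabeledImage", "ImageDataset", "AugmentConfig", "load_folder",
           "augment", "channel_stats", "normalize", "denormalize"]


@dataclass
class LabeledImage:
    """An RGB image in [0,1] with its class index and source path."""

    pixels: np.ndarray
    label: int
    source_path: str = ""


class ImageDataset:
    """In-memory image collection: (N, H, W, 3) float32 in [0,1] + labels."""

    def __init__(self, images: np.ndarray, labels: np.ndarray,
                 class_names: list[str], paths: list[str] | None = None):
        self.images = np.asarray(images, dtype=np.float32)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.class_names = list(class_names)
        self.paths = paths or [""] * len(self.labels)
        if len(self.images) != len(self.labels):
            raise ValueError("images/labels length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> LabeledImage:
        return LabeledImage(self.images[i], int(self.labels[i]), self.paths[i])

    def subset(self, indices: np.ndarray) -> "ImageDataset":
        indices = np.asarray(indices)
        return ImageDataset(self.images[indices], self.labels[indices],
                            self.class_names, [self.paths[i] for i in indices])


@dataclass
class AugmentConfig:
    """Stochastic augmentation magnitudes; all are this package's defaults."""

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    max_rotation_deg: float = 20.0
    jitter: tuple[float, float, float, float] = (0.2, 0.2, 0.2, 0.05)
    affine: tuple[float, tuple[float, float], float] = (0.1, (0.9, 1.1), 10.0)
    cutout: tuple[int, int, int, float] = (1, 32, 32, 0.0)
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.p_hflip <= 1 and 0 <= self.p_vflip <= 1):
            raise ValueError("flip probabilities must lie in [0,1]")

    @classmethod
    def light(cls) -> "AugmentConfig":
        """Flips-only profile for desk-scale runs on near-isotropic fixtures."""
        return cls(max_rotation_deg=0.0, jitter=(0.0, 0.0, 0.0, 0.0),
                   affine=(0.0, (1.0, 1.0), 0.0), cutout=(0, 0, 0, 0.0))

    @classmethod
    def none(cls) -> "AugmentConfig":
        return cls(p_hflip=0.0, p_vflip=0.0, max_rotation_deg=0.0,
                   jitter=(0.0, 0.0, 0.0, 0.0), affine=(0.0, (1.0, 1.0), 0.0),
                   cutout=(0, 0, 0, 0.0), enabled=False)


def load_folder(root_path: str | Path, image_size: int = 224) -> ImageDataset:
    """Load a class-per-subdirectory tree, resizing to ``image_size`` square.

    Class names are the sorted subdirectory names (stable lexicographic
    order). Undecodable files are skipped with a logged warning; an empty
    class folder is an error.
    """
    root = Path(root_path)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels, paths = [], [], []
    class_names = [d.name for d in class_dirs]
    for ci, cdir in enumerate(class_dirs):
        files = sorted(p for p in cdir.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if not files:
            raise ValueError(f"class folder {cdir} contains no images")
        for f in files:
            try:
                with Image.open(f) as im:
                    im = im.convert("RGB").resize(
                        (image_size, image_size), Image.Resampling.BILINEAR)
                    images.append(np.asarray(im, dtype=np.float32) / 255.0)
            except OSError:
                logger.warning("skipping undecodable image %s", f)
                continue
            labels.append(ci)
            paths.append(str(f))
    return ImageDataset(np.stack(images), np.asarray(labels), class_names, paths)


def _color_jitter(px: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    b, c, s, h = cfg.jitter
    if b > 0:
        px = px * (1.0 + rng.uniform(-b, b))
    if c > 0:
        m = px.mean()
        px = m + (px - m) * (1.0 + rng.uniform(-c, c))
    if s > 0:
        gray = px @ np.array([0.299, 0.587, 0.114])
        px = gray[..., None] + (px - gray[..., None]) * (1.0 + rng.uniform(-s, s))
    if h > 0:
        hsv = rgb_to_hsv(np.clip(px, 0, 1))
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-h, h)) % 1.0
        px = hsv_to_rgb(hsv)
    return px


def _affine(px: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    max_t, (s_lo, s_hi), max_shear = cfg.affine
    if max_t == 0 and s_lo == s_hi == 1.0 and max_shear == 0:
        return px
    hgt, wid = px.shape[:2]
    scale = rng.uniform(s_lo, s_hi)
    shear = np.deg2rad(rng.uniform(-max_shear, max_shear))
    ty = rng.uniform(-max_t, max_t) * hgt
    tx = rng.uniform(-max_t, max_t) * wid
    # inverse map: output coord -> input coord, about the image center
    mat = np.array([[1.0 / scale, np.tan(shear)], [0.0, 1.0 / scale]])
    center = np.array([hgt / 2, wid / 2])
    offset = center - mat @ (center + np.array([ty, tx]))
    out = np.empty_like(px)
    for ch in range(3):
        out[..., ch] = ndimage.affine_transform(
            px[..., ch], mat, offset=offset, order=1, mode="constant", cval=0.0)
    return out


def augment(img: LabeledImage | np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator) -> LabeledImage | np.ndarray:
    """Apply flips → rotation → color jitter → affine → cutout; clip to [0,1].

    With all probabilities and magnitudes zero the output equals the input
    exactly. The label is never changed.
    """
    is_labeled = isinstance(img, LabeledImage)
    src = img.pixels if is_labeled else img
    orig_dtype = np.asarray(src).dtype
    px = np.array(src, dtype=np.float64)
    changed = False
    if cfg.p_hflip > 0 and rng.random() < cfg.p_hflip:
        px = px[:, ::-1]
        changed = True
    if cfg.p_vflip > 0 and rng.random() < cfg.p_vflip:
        px = px[::-1]
        changed = True
    if cfg.max_rotation_deg > 0:
        angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        rot = np.empty_like(px)
        for ch in range(3):
            rot[..., ch] = ndimage.rotate(px[..., ch], angle, reshape=False,
                                          order=1, mode="constant", cval=0.0)
        px = rot
        changed = True
    if any(v > 0 for v in cfg.jitter):
        px = _color_jitter(px, cfg, rng)
        changed = True
    new = _affine(px, cfg, rng)
    changed = changed or new is not px
    px = new
    count, ch_, cw_, fill = cfg.cutout
    for _ in range(count):
        top = int(rng.integers(0, max(px.shape[0] - ch_, 0) + 1))
        left = int(rng.integers(0, max(px.shape[1] - cw_, 0) + 1))
        px[top:top + ch_, left:left + cw_] = fill
        changed = True
    if changed:
        px = np.clip(px, 0.0, 1.0)
    px = np.ascontiguousarray(px, dtype=orig_dtype)
    if is_labeled:
        return LabeledImage(px, img.label, img.source_path)
    return px


def channel_stats(dataset: ImageDataset | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and population std over all pixels of all images."""
    images = dataset.images if isinstance(dataset, ImageDataset) else np.asarray(dataset)
    if images.size == 0:
        raise ValueError("empty dataset")
    flat = images.reshape(-1, 3).astype(np.float64)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    if np.any(std == 0):
        logger.warning("degenerate channel std of 0 detected; normalize will refuse it")
    return mean, std


def normalize(img: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """(value − mean)/std per channel; refuses zero std."""
    std = np.asarray(std, dtype=np.float64)
    if np.any(std <= 0):
        raise ValueError("std entries must be positive")
    return ((np.asarray(img, dtype=np.float64) - np.asarray(mean)) / std).astype(np.float32)


def denormalize(img: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (np.asarray(img, dtype=np.float64) * np.asarray(std) + np.asarray(mean)).astype(np.float32)
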