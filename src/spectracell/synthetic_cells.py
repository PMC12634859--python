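"""Seeded generator of 8-class cell-like images for desk-scale experiments.

Each class recipe controls low-frequency cues (cell size, nucleus lobation)
and high-frequency cues (cytoplasmic granularity), so a spectral fusion
mechanism is genuinely exercised: some class pairs differ only in granule
frequency/amplitude (high band), others only in cell radius or lobe count
(low band). The default recipes loosely mimic peripheral-blood morphology
— a tiny platelet-like class, a large-round-nucleus lymphocyte-like class,
a multi-lobed neutrophil-like class, coarse-granule eosinophil-like cells,
and so on — but they are test fixtures, not biological claims.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["ClassRecipe", "SyntheticSpec", "default_recipes", "render_cell",
           "generate_dataset", "generate_arrays"]


@dataclass(frozen=True)
class ClassRecipe:
    name: str
    cell_radius_frac: float   # cell radius as a fraction of image size
    nucleus_frac: float       # nucleus area as a fraction of cell area
    n_lobes: int              # nucleus lobe count (>= 1)
    granule_freq: float       # granule texture, cycles per image
    granule_amp: float        # granule texture amplitude in [0,1] units
    base_tint: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (0 < self.cell_radius_frac <= 1 and 0 < self.nucleus_frac <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.n_lobes < 1 or self.granule_amp < 0:
            raise ValueError("need n_lobes >= 1 and granule_amp >= 0")


def default_recipes() -> list[ClassRecipe]:
    """Eight recipes with discriminative cues split across frequency bands.

    Engineered pairs: (neutrophil, ig) and (eosinophil, basophil) differ only
    in granule frequency/amplitude; (lymphocyte, erythroblast) and
    (neutrophil, monocyte) differ only in cell radius / lobe count.
    """
    return [
        ClassRecipe("basophil_like", 0.30, 0.45, 2, 32.0, 0.35, (0.85, 0.70, 0.72)),
        ClassRecipe("eosinophil_like", 0.30, 0.45, 2, 24.0, 0.30, (0.85, 0.70, 0.72)),
        ClassRecipe("erythroblast_like", 0.18, 0.85, 1, 8.0, 0.02, (0.70, 0.75, 0.90)),
        ClassRecipe("ig_like", 0.32, 0.50, 4, 16.0, 0.15, (0.80, 0.72, 0.85)),
        ClassRecipe("lymphocyte_like", 0.30, 0.85, 1, 8.0, 0.02, (0.70, 0.75, 0.90)),
        ClassRecipe("monocyte_like", 0.36, 0.50, 2, 8.0, 0.02, (0.80, 0.72, 0.85)),
        ClassRecipe("neutrophil_like", 0.32, 0.50, 4, 8.0, 0.02, (0.80, 0.72, 0.85)),
        ClassRecipe("platelet_like", 0.10, 0.50, 1, 8.0, 0.02, (0.78, 0.78, 0.88)),
    ]


@dataclass
class SyntheticSpec:
    classes: list[ClassRecipe] = field(default_factory=default_recipes)
    per_class_count: int = 100
    image_size: int = 64
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_class_count < 1:
            raise ValueError("per_class_count must be >= 1")


_BACKGROUND = np.array([0.95, 0.94, 0.96])
_NUCLEUS = np.array([0.38, 0.24, 0.52])


def render_cell(recipe: ClassRecipe, image_size: int, rng: np.random.Generator,
                noise_sigma: float = 0.02) -> np.ndarray:
    """Render one (S, S, 3) image in [0, 1] for the given class recipe.

    Background tint + jittered elliptical cell body + `n_lobes` overlapping
    nucleus disks + sinusoid-plus-speckle granule texture in the cytoplasm +
    Gaussian pixel noise, clipped to [0, 1]. Fully determined by ``rng``.
    """
    s = image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    img = np.ones((s, s, 3)) * (_BACKGROUND + rng.uniform(-0.02, 0.02, 3))

    # cell body: jittered, slightly eccentric, rotated ellipse
    r0 = recipe.cell_radius_frac * s * rng.uniform(0.9, 1.1)
    cy = s / 2 + rng.uniform(-0.05, 0.05) * s
    cx = s / 2 + rng.uniform(-0.05, 0.05) * s
    ecc = rng.uniform(0.85, 1.15)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    cell = (xr / r0) ** 2 + (yr / (r0 * ecc)) ** 2 <= 1.0
    img[cell] = np.asarray(recipe.base_tint) + rng.uniform(-0.02, 0.02, 3)

    # nucleus: n_lobes overlapping disks occupying nucleus_frac of cell area
    lobe_r = r0 * np.sqrt(recipe.nucleus_frac * ecc / recipe.n_lobes) * 0.92
    nucleus = np.zeros((s, s), dtype=bool)
    phase = rng.uniform(0, 2 * np.pi)
    for k in range(recipe.n_lobes):
        if recipe.n_lobes == 1:
            off = np.zeros(2)
        else:
            ang = phase + 2 * np.pi * k / recipe.n_lobes
            rad = 0.75 * lobe_r
            off = np.array([rad * np.cos(ang), rad * np.sin(ang)])
        ly = cy + off[1] + rng.uniform(-0.02, 0.02) * s
        lx = cx + off[0] + rng.uniform(-0.02, 0.02) * s
        nucleus |= (xx - lx) ** 2 + (yy - ly) ** 2 <= lobe_r ** 2
    nucleus &= cell
    img[nucleus] = _NUCLEUS + rng.uniform(-0.02, 0.02, 3)

    # cytoplasmic granularity: oriented sinusoid plus white speckle
    cyto = cell & ~nucleus
    if recipe.granule_amp > 0 and cyto.any():
        f = recipe.granule_freq
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        tex = np.sin(2 * np.pi * f * xx / s + p1) * np.sin(2 * np.pi * f * yy / s + p2)
        speck = rng.uniform(-1.0, 1.0, (s, s))
        grain = recipe.granule_amp * (0.6 * tex + 0.4 * speck)
        img[cyto] += grain[cyto, None]

    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, (s, s, 3))
    return np.clip(img, 0.0, 1.0)


def _item_rng(seed: int, class_idx: int, item_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, class_idx, item_idx]))


def generate_arrays(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """In-memory dataset: (images (N,S,S,3) float32, labels, class names)."""
    classes = sorted(spec.classes, key=lambda r: r.name)
    images, labels = [], []
    for ci, recipe in enumerate(classes):
        for i in range(spec.per_class_count):
            rng = _item_rng(spec.seed, ci, i)
            images.append(render_cell(recipe, spec.image_size, rng, spec.noise_sigma))
            labels.append(ci)
    return (np.asarray(images, dtype=np.float32), np.asarray(labels),
            [r.name for r in classes])


def generate_dataset(spec: SyntheticSpec, out_path: str | Path) -> Path:
    """Write a class-per-subdirectory PNG tree plus a manifest CSV.

    Regeneration with the same spec reproduces identical files byte for
    byte; every image's seed derivation is recorded in the manifest.
    """
    root = Path(out_path)
    root.mkdir(parents=True, exist_ok=True)
    classes = sorted(spec.classes, key=lambda r: r.name)
    rows = []
    for ci, recipe in enumerate(classes):
        cdir = root / recipe.name
        cdir.mkdir(exist_ok=True)
        for i in range(spec.per_class_count):
            rng = _item_rng(spec.seed, ci, i)
            img = render_cell(recipe, spec.image_size, rng, spec.noise_sigma)
            arr = np.round(img * 255.0).astype(np.uint8)
            fname = cdir / f"{recipe.name}_{i:04d}.png"
            Image.fromarray(arr).save(fname)
            rows.append({"class": recipe.name, "index": i,
                         "seed": f"{spec.seed}:{ci}:{i}",
                         "path": str(fname.relative_to(root))})
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["class", "index", "seed", "path"])
        writer.writeheader()
        writer.writerows(rows)
    return root
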