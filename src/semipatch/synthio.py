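"""Synthetic two-class histopathology-like patches and nuclei-mask concept patches.

The generator stands in for two real datasets: a binary IDC patch cohort
(IDC-positive tiles are denser in dark, hyperchromatic nuclei-like blobs than
IDC-negative tiles) and a nuclear-segmentation benchmark (image/mask pairs
with annotated nuclei). Every random choice is planted and recorded, so
morphology and texture ground truth is exact: nuclei are non-overlapping
axis-aligned ellipses, each nucleus's drawn pixel set is stored, and the
within-nucleus texture amplitude is a recorded per-patch scalar.

Intensities live in [0, 1]; Gaussian pixel noise is added after blob painting
and clipped back to range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigurationError, GenerationError
from .patchio import PatchDataset, write_patch_dir

__all__ = [
    "ClassParams",
    "SynthConfig",
    "ConceptPatch",
    "generate_patch_dataset",
    "generate_concept_dataset",
    "write_concept_dataset",
    "load_concept_dataset",
]

# Base tissue tint (pink eosin-like background) and the colour pulled out of
# it inside blobs (towards dark purple, haematoxylin-like).
_BACKGROUND_RGB = np.array([0.86, 0.72, 0.80])
_BLOB_PULL_RGB = np.array([0.55, 0.65, 0.30])


@dataclass
class ClassParams:
    """Per-class appearance: how many blobs, how big, how dark, how smooth."""

    blob_density: float = 4.0          # expected blobs per patch (Poisson mean)
    radius_range: tuple[float, float] = (2.0, 4.0)  # blob radii in pixels
    contrast: float = 0.35             # intensity pulled out of the background inside blobs
    texture_scale: float = 2.0         # smoothing sigma of the background texture field

    def validate(self) -> None:
        lo, hi = self.radius_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ConfigurationError(f"radius_range must be positive and ordered, got {self.radius_range}")
        if self.blob_density < 0:
            raise ConfigurationError("blob_density must be non-negative")
        if not 0.0 <= self.contrast <= 1.0:
            raise ConfigurationError("contrast must lie in [0, 1]")


def default_class_params() -> dict[int, ClassParams]:
    """IDC-negative (0): sparse faint blobs; IDC-positive (1): dense dark blobs."""
    return {
        0: ClassParams(blob_density=3.0, radius_range=(2.0, 4.0), contrast=0.22, texture_scale=2.0),
        1: ClassParams(blob_density=9.0, radius_range=(2.5, 5.0), contrast=0.45, texture_scale=1.5),
    }


@dataclass
class SynthConfig:
    patch_size: int = 32
    n_per_class: int = 100
    class_params: dict[int, ClassParams] = field(default_factory=default_class_params)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.patch_size < 16:
            raise ConfigurationError(f"patch_size must be >= 16, got {self.patch_size}")
        if self.n_per_class < 1:
            raise ConfigurationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if not self.class_params:
            raise ConfigurationError("class_params must not be empty")
        for params in self.class_params.values():
            params.validate()


@dataclass
class ConceptPatch:
    """An image/mask pair with the exact planted nuclei record.

    planted keys: n_nuclei, semi_axes [(a, b)...], eccentricities, pixel_areas
    (exact drawn pixel count per nucleus), texture_contrast.
    """

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    mask: np.ndarray   # (H, W) uint8, strictly 0/1
    planted: dict

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ConfigurationError("image and mask spatial dimensions must match")
        vals = set(np.unique(self.mask))
        if not vals <= {0, 1}:
            raise ConfigurationError(f"mask must be strictly binary, found values {sorted(vals)}")


# ---------------------------------------------------------------------------
# Two-class patch generation
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, size: int, texture_scale: float) -> np.ndarray:
    field_ = gaussian_filter(rng.normal(size=(size, size)), sigma=texture_scale)
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd * 0.04
    return np.clip(_BACKGROUND_RGB[None, None, :] + field_[:, :, None], 0.0, 1.0)


def _paint_blobs(img: np.ndarray, rng: np.random.Generator, params: ClassParams) -> None:
    size = img.shape[0]
    n_blobs = rng.poisson(params.blob_density)
    lo, hi = params.radius_range
    for _ in range(n_blobs):
        r = rng.uniform(lo, hi)
        cy, cx = rng.uniform(0, size, size=2)
        rr, cc = draw_ellipse(cy, cx, r, r, shape=(size, size))
        if rr.size == 0:
            continue
        depth = params.contrast * rng.uniform(0.7, 1.0)
        img[rr, cc] = np.clip(img[rr, cc] - depth * _BLOB_PULL_RGB[None, :], 0.0, 1.0)


def generate_patch_dataset(config: SynthConfig) -> PatchDataset:
    """Generate ``2 * n_per_class`` labelled RGB patches (classes 0 and 1).

    Identical configs (including seed) give bit-identical pixel arrays.
    """
    rng = np.random.default_rng(config.seed)
    images, labels, ids = [], [], []
    for label in sorted(config.class_params):
        params = config.class_params[label]
        for i in range(config.n_per_class):
            img = _background(rng, config.patch_size, params.texture_scale)
            _paint_blobs(img, rng, params)
            if config.noise_sd > 0:
                img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(label)
            ids.append(f"synth_class{label}_{i:05d}")
    return PatchDataset.from_images(np.stack(images), labels=np.array(labels), ids=ids)


# ---------------------------------------------------------------------------
# Concept patches (image + nuclei mask)
# ---------------------------------------------------------------------------

def generate_concept_dataset(
    config: SynthConfig,
    n_patches: int,
    n_nuclei_range: tuple[int, int] = (1, 6),
    radius_range: tuple[float, float] = (2.0, 4.5),
    ecc_range: tuple[float, float] = (0.0, 0.8),
    texture_range: tuple[float, float] = (0.05, 0.40),
    max_retries: int = 200,
) -> list[ConceptPatch]:
    """Generate image/mask concept patches with non-overlapping elliptical nuclei.

    Nuclei are axis-aligned ellipses with major semi-axis drawn from
    ``radius_range`` and eccentricity from ``ecc_range``; placement is
    rejection-sampled so masks never overlap (morphology ground truth is
    exact). Inside each nucleus a fine texture of per-patch amplitude drawn
    from ``texture_range`` is painted, planting the texture-contrast concept.
    """
    if n_patches < 1:
        raise ConfigurationError(f"n_patches must be >= 1, got {n_patches}")
    lo, hi = radius_range
    if lo <= 0 or lo > hi:
        raise ConfigurationError(f"radius_range must be positive and ordered, got {radius_range}")
    if n_nuclei_range[0] < 0 or n_nuclei_range[0] > n_nuclei_range[1]:
        raise ConfigurationError(f"invalid n_nuclei_range {n_nuclei_range}")
    rng = np.random.default_rng(config.seed)
    size = config.patch_size
    patches = []
    for p in range(n_patches):
        n_nuclei = int(rng.integers(n_nuclei_range[0], n_nuclei_range[1] + 1))
        texture = float(rng.uniform(*texture_range))
        mask = np.zeros((size, size), dtype=np.uint8)
        img = _background(rng, size, texture_scale=2.0)
        semi_axes, eccs, areas = [], [], []
        for _ in range(n_nuclei):
            placed = False
            for _attempt in range(max_retries):
                a = rng.uniform(lo, hi)
                e = rng.uniform(*ecc_range)
                b = a * np.sqrt(1.0 - e**2)
                cy = rng.uniform(a + 1, size - a - 1)
                cx = rng.uniform(b + 1, size - b - 1)
                rr, cc = draw_ellipse(cy, cx, a, b, shape=(size, size))
                if rr.size == 0:
                    continue
                # forbid touching: reject if any drawn pixel or 4-neighbour is set
                if mask[rr, cc].any() or _touches(mask, rr, cc, size):
                    continue
                mask[rr, cc] = 1
                depth = 0.45
                img[rr, cc] = np.clip(img[rr, cc] - depth * _BLOB_PULL_RGB[None, :], 0.0, 1.0)
                img[rr, cc] += rng.normal(0.0, texture, size=(rr.size, 1)) * np.array([[1.0, 1.0, 1.0]]) * 0.5
                semi_axes.append((float(a), float(b)))
                eccs.append(float(e))
                areas.append(int(rr.size))
                placed = True
                break
            if not placed:
                raise GenerationError(
                    f"could not place nucleus in patch {p} after {max_retries} retries; "
                    "reduce n_nuclei_range or radius_range"
                )
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        patches.append(
            ConceptPatch(
                image=np.clip(img, 0.0, 1.0),
                mask=mask,
                planted={
                    "n_nuclei": n_nuclei,
                    "semi_axes": semi_axes,
                    "eccentricities": eccs,
                    "pixel_areas": areas,
                    "texture_contrast": texture,
                },
            )
        )
    return patches


def _touches(mask: np.ndarray, rr: np.ndarray, cc: np.ndarray, size: int) -> bool:
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        r2 = np.clip(rr + dy, 0, size - 1)
        c2 = np.clip(cc + dx, 0, size - 1)
        if mask[r2, c2].any():
            return True
    return False


# ---------------------------------------------------------------------------
# Concept patch I/O (paired *_img.png / *_mask.png)
# ---------------------------------------------------------------------------

def write_concept_dataset(patches: list[ConceptPatch], path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, cp in enumerate(patches):
        img = np.clip(np.round(cp.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(img).save(path / f"concept_{i:04d}_img.png")
        Image.fromarray((cp.mask * 255).astype(np.uint8)).save(path / f"concept_{i:04d}_mask.png")
    return path


def load_concept_dataset(path: str | Path) -> list[ConceptPatch]:
    path = Path(path)
    patches = []
    for img_file in sorted(path.glob("*_img.png")):
        mask_file = img_file.with_name(img_file.name.replace("_img.png", "_mask.png"))
        if not mask_file.exists():
            raise ConfigurationError(f"missing mask pair for {img_file}")
        with Image.open(img_file) as im:
            image = np.asarray(im.convert("RGB"), dtype=float) / 255.0
        with Image.open(mask_file) as im:
            mask = (np.asarray(im.convert("L")) > 127).astype(np.uint8)
        patches.append(ConceptPatch(image=image, mask=mask, planted={}))
    return patches


def write_synthetic_study(config: SynthConfig, out_dir: str | Path, unlabelled_fraction: float = 0.0) -> Path:
    """Generate and write a patch study to disk (CLI entry point helper)."""
    ds = generate_patch_dataset(config)
    if unlabelled_fraction > 0:
        rng = np.random.default_rng(config.seed + 1)
        strip = rng.random(len(ds)) < unlabelled_fraction
        ds.labels[strip] = -1
    return write_patch_dir(ds, out_dir)
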