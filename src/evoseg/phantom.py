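"""Synthetic B-mode ultrasound phantoms with ground-truth masks.

Real B-mode liver images have three statistical features the segmentation
task depends on: granular multiplicative speckle texture, intensity decay
with depth (attenuation), and a field of interest whose echogenicity
differs from the surrounding tissue.  The generator reproduces exactly
these: a piecewise echogenicity map (background 1.0, one contiguous
elevated-echogenicity blob), multiplied by a Rayleigh-derived speckle
field and a per-row attenuation profile, optionally darkened by a shadow
wedge widening with depth.

The blob is a randomly oriented ellipse with a low-frequency radial
perturbation of its contour, emulating a smooth manually drawn
field-of-interest boundary.  Being star-shaped about its center, the blob
is always one 4-connected region.

Everything is driven by a single seed, so datasets are bit-reproducible,
whether generated in memory or written as 8-bit PNG pairs with a manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "PhantomConfig",
    "SegmentationDataset",
    "generate_phantom",
    "generate_arrays",
    "generate_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom generator.

    ``blob_echogenicity_contrast`` is the multiplicative brightness of the
    field of interest relative to background (>1 = hyperechoic, as in a
    steatotic liver against muscle).  ``speckle_shape`` scales the
    amplitude of the multiplicative speckle (0 = noise-free two-level
    image, ~1 = fully developed Rayleigh texture).
    ``attenuation_per_row`` is the fractional intensity loss per pixel row.
    ``boundary_roughness`` is the relative amplitude of the low-frequency
    radial perturbation of the blob contour.
    """

    height: int = 64
    width: int = 64
    blob_echogenicity_contrast: float = 1.6
    blob_area_fraction: float = 0.15
    speckle_shape: float = 0.7
    attenuation_per_row: float = 0.004
    shadow_probability: float = 0.2
    boundary_roughness: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom must be at least 8x8 pixels")
        if not 0.05 <= self.blob_area_fraction <= 0.4:
            raise ValueError("blob_area_fraction must be in [0.05, 0.4]")
        if self.blob_echogenicity_contrast <= 0:
            raise ValueError("blob_echogenicity_contrast must be positive")
        for name in ("speckle_shape", "attenuation_per_row",
                     "shadow_probability", "boundary_roughness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def digest(self) -> str:
        """Short stable hash of the configuration, for manifests."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class SegmentationDataset:
    """Aligned image/mask pairs as arrays.

    ``images``: float32 in [0, 1], shape (n, H, W); ``masks``: uint8 in
    {0, 1}, same shape.
    """

    images: np.ndarray
    masks: np.ndarray

    def __post_init__(self) -> None:
        if self.images.shape != self.masks.shape or self.images.ndim != 3:
            raise ValueError("images and masks must share shape (n, H, W)")
        self.images = self.images.astype(np.float32)
        self.masks = (self.masks > 0).astype(np.uint8)

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, idx) -> "SegmentationDataset":
        return SegmentationDataset(self.images[idx], self.masks[idx])


# Rayleigh scale giving unit mean: mean = scale * sqrt(pi/2).
_RAYLEIGH_UNIT_SCALE = float(np.sqrt(2.0 / np.pi))


def _blob_mask(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.height, cfg.width
    target_area = cfg.blob_area_fraction * h * w
    aspect = rng.uniform(0.55, 0.95)
    a = float(np.sqrt(target_area / (np.pi * aspect)))  # semi-major axis, px
    b = aspect * a
    theta = rng.uniform(0.0, np.pi)
    # Low-frequency radial perturbation of the unit contour.
    ks = np.array([2, 3, 4])
    amps = cfg.boundary_roughness * rng.uniform(0.3, 1.0, size=3) / ks
    phases = rng.uniform(0.0, 2 * np.pi, size=3)
    margin = a * (1.0 + float(np.sum(amps))) + 1.0
    if 2 * margin >= min(h, w):
        raise ValueError(
            "field-of-interest blob cannot fit: "
            f"needs radius {margin:.1f} px inside a {h}x{w} image"
        )
    cy = rng.uniform(margin, h - 1 - margin)
    cx = rng.uniform(margin, w - 1 - margin)
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    rho = np.sqrt(u * u + v * v)
    phi = np.arctan2(v, u)
    contour = 1.0
    for k, amp, ph in zip(ks, amps, phases):
        contour = contour + amp * np.cos(k * phi + ph)
    return (rho <= contour).astype(np.uint8)


def generate_phantom(
    cfg: PhantomConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One phantom: (image float32 in [0, 1], mask uint8 in {0, 1}).

    Fully reproducible: the same config (or the same generator state)
    yields a bit-identical pair.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mask = _blob_mask(cfg, rng)
    echo = np.where(mask > 0, cfg.blob_echogenicity_contrast, 1.0)
    image = echo.astype(np.float64)
    if cfg.speckle_shape > 0:
        rayleigh = rng.rayleigh(_RAYLEIGH_UNIT_SCALE, size=image.shape)
        speckle = 1.0 + cfg.speckle_shape * (rayleigh - 1.0)
        image = image * np.clip(speckle, 0.05, None)
    if cfg.attenuation_per_row > 0:
        rows = np.arange(cfg.height, dtype=np.float64)
        image = image * ((1.0 - cfg.attenuation_per_row) ** rows)[:, None]
    if cfg.shadow_probability > 0 and rng.random() < cfg.shadow_probability:
        apex = rng.uniform(0, cfg.width)
        half_w0 = rng.uniform(1.0, 3.0)
        slope = rng.uniform(0.05, 0.15)
        yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
        wedge = np.abs(xx - apex) <= (half_w0 + slope * yy)
        image = np.where(wedge, image * 0.45, image)
    image = image / image.max()
    return image.astype(np.float32), mask


def _pair_seeds(master_seed: int, n: int) -> np.ndarray:
    # Independent, order-stable per-pair seeds below 2**31.
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return (state % (2**31)).astype(np.int64)


def generate_arrays(cfg: PhantomConfig, n: int) -> SegmentationDataset:
    """Generate ``n`` phantoms in memory as a :class:`SegmentationDataset`.

    Uses the same per-pair seed derivation as :func:`generate_dataset`, so
    in-memory arrays match what would be written to disk (before 8-bit
    quantization).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = _pair_seeds(cfg.seed, n)
    images = np.empty((n, cfg.height, cfg.width), dtype=np.float32)
    masks = np.empty((n, cfg.height, cfg.width), dtype=np.uint8)
    for i, s in enumerate(seeds):
        img, msk = generate_phantom(replace(cfg, seed=int(s)))
        images[i] = img
        masks[i] = msk
    return SegmentationDataset(images, masks)


def generate_dataset(cfg: PhantomConfig, n: int, out_dir) -> pd.DataFrame:
    """Write ``n`` image/mask PNG pairs plus a manifest CSV.

    Files are ``phantom_{i:04d}.png`` / ``phantom_{i:04d}_mask.png`` (8-bit
    grayscale; masks 0/255).  The manifest lists stem, per-pair seed and
    the config hash; re-running with the same arguments reproduces
    byte-identical files.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _pair_seeds(cfg.seed, n)
    rows = []
    for i, s in enumerate(seeds):
        img, msk = generate_phantom(replace(cfg, seed=int(s)))
        stem = f"phantom_{i:04d}"
        iio.imwrite(out / f"{stem}.png", np.round(img * 255).astype(np.uint8))
        iio.imwrite(out / f"{stem}_mask.png", (msk * 255).astype(np.uint8))
        rows.append({"stem": stem, "seed": int(s), "config_hash": cfg.digest()})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_dataset(directory) -> SegmentationDataset:
    """Load paired PNGs from a directory into arrays.

    Pairing is by file stem (``X.png`` with ``X_mask.png``); an image
    without its mask, or vice versa, is an error naming the stem.  Images
    are rescaled to [0, 1]; masks binarized at nonzero.
    """
    directory = Path(directory)
    mask_stems = {
        p.name[: -len("_mask.png")] for p in directory.glob("*_mask.png")
    }
    image_stems = {
        p.stem for p in directory.glob("*.png") if not p.name.endswith("_mask.png")
    }
    orphans = sorted(mask_stems ^ image_stems)
    if orphans:
        raise ValueError(f"unpaired image/mask stems: {orphans}")
    if not image_stems:
        raise ValueError(f"no image/mask pairs found in {directory}")
    images, masks = [], []
    for stem in sorted(image_stems):
        img = np.asarray(iio.imread(directory / f"{stem}.png"), dtype=np.float32)
        msk = np.asarray(iio.imread(directory / f"{stem}_mask.png"))
        if img.shape != msk.shape:
            raise ValueError(f"image/mask dimensions differ for stem '{stem}'")
        images.append(img / 255.0)
        masks.append((msk > 0).astype(np.uint8))
    shapes = {a.shape for a in images}
    if len(shapes) != 1:
        raise ValueError(f"images in {directory} have mixed dimensions: {shapes}")
    return SegmentationDataset(np.stack(images), np.stack(masks))
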