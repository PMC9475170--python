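"""Synthetic ultrasound-like nodule phantoms with exact ground truth.

The generator emulates the qualitative appearance of B-mode thyroid
frames: a smoothly varying echogenic background carrying multiplicative
Gamma speckle, one or more hypoechoic (darker) nodules with star-convex,
harmonically perturbed boundaries, boundary blur so the image edge is
ambiguous while the label is not, and occasional bright calcification
spots.  It is a statistical phantom, not a wave-propagation simulation;
its purpose is to give the segmentation pipeline a learnable, fully
reproducible task with known masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .data import ImagePair

logger = logging.getLogger(__name__)


@dataclass
class PhantomConfig:
    """Generative parameters of the speckle/nodule model.

    ``contrast`` is the nodule-to-background mean intensity ratio (< 1:
    hypoechoic).  ``irregularity_harmonics``/``irregularity_amplitude``
    control the radial harmonics perturbing the boundary circle;
    amplitude 0 gives a perfect ellipse.  ``speckle_shape`` is the Gamma
    shape parameter of the unit-mean multiplicative speckle (smaller =
    noisier).  ``blur_sigma`` is in pixels.
    """

    size: int = 64
    n_nodules: int = 1
    contrast: float = 0.55
    irregularity_harmonics: int = 4
    irregularity_amplitude: float = 0.12
    blur_sigma: float = 1.5
    speckle_shape: float = 8.0
    calcification_rate: float = 0.3
    radius_fraction: tuple[float, float] = (0.14, 0.24)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.contrast < 1:
            raise ValueError("contrast must lie in (0, 1): nodules are hypoechoic")
        if self.size < 16:
            raise ValueError("size must be >= 16")
        lo, hi = self.radius_fraction
        if not 0 < lo <= hi < 0.5:
            raise ValueError("radius_fraction must satisfy 0 < lo <= hi < 0.5")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")


def _nodule_mask(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Binary mask of one star-convex nodule, fully inside the frame."""
    size = cfg.size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    for attempt in range(8):
        shrink = 0.85 ** attempt
        r0 = rng.uniform(*cfg.radius_fraction) * size * shrink
        ecc = rng.uniform(0.7, 1.0)          # ry/rx, mild ellipticity
        rx, ry = r0, r0 * ecc
        margin = max(rx, ry) * (1 + cfg.irregularity_amplitude) + 2
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        amps = cfg.irregularity_amplitude * rng.uniform(0.3, 1.0, cfg.irregularity_harmonics)
        amps /= np.arange(1, cfg.irregularity_harmonics + 1)  # damp high harmonics
        phases = rng.uniform(0, 2 * np.pi, cfg.irregularity_harmonics)

        u, v = (xx - cx) / rx, (yy - cy) / ry
        rho = np.hypot(u, v)
        theta = np.arctan2(v, u)
        boundary = np.ones_like(rho)
        for j, (a, phi) in enumerate(zip(amps, phases), start=1):
            boundary += a * np.sin(j * theta + phi)
        mask = rho <= boundary
        border = mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
        if mask.any() and not border:
            return mask
        logger.info("nodule exceeded bounds; regenerating with shrunken radius "
                    "(attempt %d)", attempt + 1)
    raise RuntimeError("could not place a nodule inside the frame")


def generate_phantom(config: PhantomConfig) -> ImagePair:
    """One phantom image (float in [0, 1]) with its binary mask.

    The same config (same seed) always yields a bit-identical pair.
    """
    rng = np.random.default_rng(config.seed)
    size = config.size

    # smooth echogenic background around a bright baseline
    low_freq = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 8.0)
    if low_freq.std() > 0:
        low_freq = low_freq / low_freq.std() * 0.06
    background = 0.72 + low_freq

    mask = np.zeros((size, size), dtype=bool)
    for _ in range(config.n_nodules):
        mask |= _nodule_mask(config, rng)

    # hypoechoic interior; the intensity edge is blurred, the label is not
    attenuation = 1.0 - (1.0 - config.contrast) * ndimage.gaussian_filter(
        mask.astype(np.float64), config.blur_sigma)
    field = background * attenuation

    n_calc = rng.poisson(config.calcification_rate)
    inside = np.argwhere(mask)
    for _ in range(min(n_calc, len(inside))):
        cy, cx = inside[rng.integers(len(inside))]
        spot = np.zeros((size, size))
        spot[cy, cx] = 1.0
        field += 0.5 * ndimage.gaussian_filter(spot, 0.8) * (2 * np.pi * 0.8 ** 2)

    speckle = rng.gamma(config.speckle_shape, 1.0 / config.speckle_shape, (size, size))
    image = field * speckle
    image = np.clip(image / max(image.max(), 1e-12), 0.0, 1.0)
    return ImagePair(image.astype(np.float32), mask.astype(np.uint8))


def generate_batch(n: int, config: PhantomConfig) -> list[ImagePair]:
    """``n`` phantoms with per-item seeds derived from ``config.seed``."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n)
    return [generate_phantom(replace(config, seed=int(s))) for s in seeds]


def generate_dataset(n: int, config: PhantomConfig, out_dir) -> pd.DataFrame:
    """Write ``n`` image/mask PNG pairs plus a CSV manifest.

    The manifest records filename, per-item seed, nodule area (foreground
    pixel count) and centroid.  Re-running with the same master seed
    reproduces all files byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(n)
    rows = []
    for i, s in enumerate(seeds):
        pair = generate_phantom(replace(config, seed=int(s)))
        img_name, mask_name = f"phantom_{i:04d}.png", f"phantom_{i:04d}_mask.png"
        Image.fromarray(np.round(pair.image * 255).astype(np.uint8)).save(out_dir / img_name)
        Image.fromarray(pair.mask * np.uint8(255)).save(out_dir / mask_name)
        ys, xs = np.nonzero(pair.mask)
        rows.append({
            "image": img_name,
            "mask": mask_name,
            "seed": int(s),
            "nodule_area": int(pair.mask.sum()),
            "centroid_row": float(ys.mean()) if len(ys) else float("nan"),
            "centroid_col": float(xs.mean()) if len(xs) else float("nan"),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
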