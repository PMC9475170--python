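"""Dataset readers/writers: PNG image-mask pairs, manifests, configs.

Images are 8-bit grayscale PNG (RGB converted by luminance), scaled to
[0, 1] and resized bilinearly; masks are {0, 255} PNG, resized with
nearest-neighbour and binarised at 127 so labels stay crisp.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .data import ImagePair

MASK_THRESHOLD = 127


def load_image(path, target_size: int | None = None) -> np.ndarray:
    """Grayscale float image in [0, 1], optionally bilinearly resized."""
    try:
        img = Image.open(path)
    except OSError as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    img = img.convert("L")
    if target_size is not None:
        img = img.resize((target_size, target_size), Image.BILINEAR)
    return np.asarray(img, dtype=np.float32) / 255.0


def load_mask(path, target_size: int | None = None) -> np.ndarray:
    """Binary {0, 1} mask from a {0, 255} PNG (nearest-neighbour resize)."""
    try:
        img = Image.open(path)
    except OSError as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    img = img.convert("L")
    if target_size is not None:
        img = img.resize((target_size, target_size), Image.NEAREST)
    arr = np.asarray(img)
    return (arr > MASK_THRESHOLD).astype(np.uint8)


def load_pair(image_path, mask_path, target_size: int | None = None) -> ImagePair:
    """Load an image/mask pair, resized to ``target_size`` x ``target_size``."""
    image = load_image(image_path, target_size)
    mask = load_mask(mask_path, target_size)
    if image.shape != mask.shape:
        raise IOError(
            f"image {image.shape} and mask {mask.shape} disagree after resize "
            f"({image_path} / {mask_path})")
    return ImagePair(image, mask)


def save_pair(pair: ImagePair, image_path, mask_path) -> None:
    Image.fromarray(np.round(pair.image * 255).astype(np.uint8)).save(image_path)
    Image.fromarray(pair.mask * np.uint8(255)).save(mask_path)


def load_manifest(manifest_path, target_size: int | None = None) -> list[ImagePair]:
    """Load every pair listed in a dataset manifest CSV.

    The manifest has ``image`` and ``mask`` columns with paths relative
    to its own directory; duplicates and missing files are errors.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    for col in ("image", "mask"):
        if col not in df.columns:
            raise IOError(f"manifest missing required column {col!r}")
        if df[col].duplicated().any():
            raise IOError(f"manifest has duplicate {col} paths")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(load_pair(root / row["image"], root / row["mask"], target_size))
    return pairs


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config_snapshot(config: dict, out_dir, name: str = "config_snapshot.json") -> Path:
    """Record the exact configuration next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, default=str)
    return path
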