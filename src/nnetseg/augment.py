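"""Geometric augmentation and six-view test-time augmentation (TTA).

The transform set is the dihedral subset used for ultrasound frames:
identity, rotations by 90/180/270 degrees, horizontal flip and vertical
flip.  Every member has its exact inverse in the set, and on integer
grids apply-then-invert is bit-exact, so TTA predictions can be aligned
losslessly before averaging.
"""

from __future__ import annotations

import numpy as np

TRANSFORM_NAMES = ("identity", "rot90", "rot180", "rot270", "hflip", "vflip")

_INVERSE = {
    "identity": "identity",
    "rot90": "rot270",
    "rot180": "rot180",
    "rot270": "rot90",
    "hflip": "hflip",
    "vflip": "vflip",
}


def apply_transform(arr: np.ndarray, name: str) -> np.ndarray:
    """Apply a named transform to the last two (row, column) axes."""
    arr = np.asarray(arr)
    if name in ("rot90", "rot270") and arr.shape[-2] != arr.shape[-1]:
        raise ValueError(f"{name} requires square grids, got {arr.shape[-2:]}")
    if name == "identity":
        return arr.copy()
    if name == "rot90":
        return np.rot90(arr, 1, axes=(-2, -1)).copy()
    if name == "rot180":
        return np.rot90(arr, 2, axes=(-2, -1)).copy()
    if name == "rot270":
        return np.rot90(arr, 3, axes=(-2, -1)).copy()
    if name == "hflip":
        return np.flip(arr, axis=-1).copy()
    if name == "vflip":
        return np.flip(arr, axis=-2).copy()
    raise ValueError(f"unknown transform {name!r}")


def inverse_transform(arr: np.ndarray, name: str) -> np.ndarray:
    """Undo :func:`apply_transform` exactly."""
    return apply_transform(arr, _INVERSE[name])


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 rng: np.random.Generator | int) -> tuple[np.ndarray, np.ndarray]:
    """Apply one transform, drawn uniformly from the six, to both grids.

    ``rng`` is a Generator or a seed; a fixed seed replays the same draw.
    """
    image, mask = np.asarray(image), np.asarray(mask)
    if image.shape[-2:] != mask.shape[-2:]:
        raise ValueError("image and mask spatial shapes differ")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    name = TRANSFORM_NAMES[rng.integers(len(TRANSFORM_NAMES))]
    return apply_transform(image, name), apply_transform(mask, name)


def tta_predict(predictor, image: np.ndarray) -> np.ndarray:
    """Six-view TTA: predict each transformed copy, inverse-align, average.

    ``predictor`` maps an (N, 1, H, W) batch to probability maps of the
    same shape (e.g. ``model.predict``); a model object exposing
    ``.predict`` is also accepted.  Exactly six forward passes are made
    per image and the aligned maps are averaged element-wise, before any
    thresholding.
    """
    if hasattr(predictor, "predict"):
        predictor = predictor.predict
    image = np.asarray(image)
    squeeze = image.ndim == 2
    batch = image[None, None] if squeeze else image
    if batch.ndim != 4:
        raise ValueError(f"expected (N,1,H,W) or (H,W) input, got {image.shape}")
    acc = None
    for name in TRANSFORM_NAMES:
        pred = predictor(apply_transform(batch, name))
        pred = np.asarray(pred)
        if pred.shape != batch.shape:
            raise ValueError(
                f"predictor output {pred.shape} does not match input {batch.shape}")
        aligned = inverse_transform(pred, name)
        acc = aligned if acc is None else acc + aligned
    out = acc / len(TRANSFORM_NAMES)
    return out[0, 0] if squeeze else out
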