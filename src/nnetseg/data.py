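"""In-memory containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ImagePair:
    """A grayscale image in [0, 1] and its binary {0, 1} nodule mask,
    with identical spatial dimensions."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} shapes differ")
        if self.image.ndim != 2:
            raise ValueError("ImagePair holds single 2-D grids")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary {0, 1}")
        self.mask = self.mask.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def stack_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Stack ImagePairs into (N, 1, H, W) image and mask batches."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair sequence")
    x = np.stack([p.image for p in pairs]).astype(np.float32)[:, None]
    y = np.stack([p.mask for p in pairs]).astype(np.float32)[:, None]
    return x, y
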