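"""Resizing and intensity normalization ahead of the network.

Dermoscopic images vary in size; the network consumes a fixed 256x256 frame.
Images are resampled bilinearly, masks with nearest-neighbor so they remain
strictly binary. Intensity normalization is per image: subtract the image
mean and divide by the image standard deviation, computed jointly over all
three channels, which centers the input around zero with unit spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _resize

__all__ = ["TARGET_SIZE", "NormalizedImage", "resize_pair", "normalize"]

TARGET_SIZE = 256


@dataclass
class NormalizedImage:
    """Zero-mean, unit-variance float image plus the statistics removed."""

    pixels: np.ndarray  # H x W x 3 float32
    source_mean: float
    source_sd: float


def resize_pair(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    size: int = TARGET_SIZE,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Resize an RGB image (bilinear) and optionally its mask (nearest).

    The mask is re-binarized to {0, 1} after resampling and must share the
    image's height and width.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != image.shape[:2]:
            raise ValueError(
                f"mask shape {mask.shape} does not match image {image.shape[:2]}"
            )
    if image.shape[0] == size and image.shape[1] == size:
        out_img = image.copy()
    else:
        out_img = _resize(
            image.astype(np.float64),
            (size, size),
            order=1,
            preserve_range=True,
            anti_aliasing=False,
        )
        out_img = np.clip(np.rint(out_img), 0, 255).astype(np.uint8)
    out_mask = None
    if mask is not None:
        if mask.shape == (size, size):
            out_mask = (mask > 0).astype(np.uint8)
        else:
            resampled = _resize(
                mask.astype(np.float64),
                (size, size),
                order=0,
                preserve_range=True,
                anti_aliasing=False,
            )
            out_mask = (resampled > 0.5).astype(np.uint8)
    return out_img, out_mask


def normalize(image: np.ndarray) -> NormalizedImage:
    """Standardize an RGB image to zero mean and unit variance.

    Statistics are taken over all pixels and channels of the single image. A
    constant image (zero standard deviation) maps to all zeros.
    """
    arr = np.asarray(image, dtype=np.float64)
    mean = float(arr.mean())
    sd = float(arr.std())
    if sd == 0.0:
        return NormalizedImage(np.zeros(arr.shape, dtype=np.float32), mean, 0.0)
    return NormalizedImage(((arr - mean) / sd).astype(np.float32), mean, sd)
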