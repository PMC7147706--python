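"""PNG/JPEG image I/O helpers (PIL-backed)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_rgb", "write_rgb", "read_mask", "write_mask"]


def read_rgb(path: str | Path, strict: bool = True) -> np.ndarray:
    """Load an image as H x W x 3 uint8; ``strict`` rejects non-RGB files."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 3 or arr.shape[2] != 3:
        if strict:
            raise ValueError(
                f"{path}: expected a 3-channel RGB image, got shape {arr.shape}"
            )
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
    return arr.astype(np.uint8)


def write_rgb(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a mask PNG as {0,1} uint8 (any nonzero byte is foreground)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0,1} mask as an 8-bit {0,255} PNG."""
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, mode="L").save(path)
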