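"""Morphological hair detection and fast-marching inpainting.

Dermoscopic images frequently contain hair shafts that occlude the lesion and
confuse segmentation networks. The removal algorithm is:

1. convert RGB to grayscale (ITU-R BT.601 luminance);
2. black top-hat filter with a 17x17 cross structuring element — the
   grayscale closing of the image minus the image, which responds strongly on
   thin dark structures such as hairs;
3. threshold the top-hat response (strictly above 10 on the 0-255 scale) to a
   binary hair mask;
4. fill the masked pixels by fast-marching inpainting: pixels are visited in
   order of increasing distance from the mask boundary and each is replaced
   by a normalized weighted average of already-known pixels in a small
   neighborhood, with Telea-style direction, distance and level-set weights.

The inpainted value is a convex combination of known neighbor values, so each
filled pixel always lies inside the intensity range of its contributors, and
pixels outside the mask are never touched.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "InpaintConfig",
    "to_grayscale",
    "cross_element",
    "close",
    "black_tophat",
    "hair_mask",
    "inpaint_fmm",
    "remove_hair",
]

#: ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])

DEFAULT_SE_SIZE = 17
DEFAULT_THRESHOLD = 10


@dataclass(frozen=True)
class InpaintConfig:
    """Knobs of the hair-removal pipeline.

    ``radius`` is the half-width of the known-pixel neighborhood averaged when
    filling a masked pixel; ``threshold`` is applied to the black top-hat
    response on the 0-255 scale.
    """

    radius: int = 5
    threshold: int = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("inpainting radius must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB -> 8-bit luminance: 0.299 R + 0.587 G + 0.114 B, rounded."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("to_grayscale expects an H x W x 3 image")
    gray = image.astype(np.float64) @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def cross_element(size: int = DEFAULT_SE_SIZE) -> np.ndarray:
    """Odd-sized cross (plus-shaped) structuring element as a binary grid."""
    if size < 1 or size % 2 == 0:
        raise ValueError("structuring element size must be odd and positive")
    se = np.zeros((size, size), dtype=bool)
    mid = size // 2
    se[mid, :] = True
    se[:, mid] = True
    return se


def close(image: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Grayscale closing: dilation then erosion with the same footprint.

    Borders are handled by edge replication so no artificial dark ring is
    created at the frame; closing is extensive (output >= input everywhere).
    """
    image = np.asarray(image)
    dilated = ndimage.grey_dilation(image, footprint=se, mode="nearest")
    return ndimage.grey_erosion(dilated, footprint=se, mode="nearest")


def black_tophat(image: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Closing minus the image; highlights dark detail thinner than the element."""
    image = np.asarray(image)
    return close(image, se).astype(np.int16) - image.astype(np.int16)


def hair_mask(tophat: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binarize the top-hat response: foreground strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return (np.asarray(tophat) > threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# fast-marching inpainting

_KNOWN, _BAND, _INSIDE = 0, 1, 2


def inpaint_fmm(image: np.ndarray, mask: np.ndarray, cfg: InpaintConfig | None = None) -> np.ndarray:
    """Fill masked pixels of an RGB image by fast-marching inpainting.

    Masked pixels are processed in order of increasing arrival time ``T`` of a
    front marching inward from the mask boundary (Eikonal equation solved with
    the standard upwind update). Each pixel is set to the weighted average of
    the known (original or already filled) pixels within ``cfg.radius``, with
    weight = direction factor x 1/d^2 distance factor x level-set proximity
    factor. Ties in arrival time are broken by insertion order, making the
    result deterministic for a fixed input.
    """
    cfg = cfg or InpaintConfig()
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("inpaint_fmm expects an H x W x 3 image")
    if mask.shape != image.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image {image.shape[:2]}")
    mask = mask > 0
    if not mask.any():
        return image.copy()
    if mask.all():
        raise ValueError("cannot inpaint an all-foreground mask: no known pixels")

    h, w = mask.shape
    out = image.astype(np.float64).copy()
    flags = np.where(mask, _INSIDE, _KNOWN).astype(np.uint8)
    tmap = np.where(mask, np.inf, 0.0)

    def eikonal(i: int, j: int) -> float:
        best = np.inf
        for (i1, j1), (i2, j2) in (
            ((i - 1, j), (i, j - 1)),
            ((i - 1, j), (i, j + 1)),
            ((i + 1, j), (i, j - 1)),
            ((i + 1, j), (i, j + 1)),
        ):
            t1 = tmap[i1, j1] if 0 <= i1 < h and 0 <= j1 < w and flags[i1, j1] == _KNOWN else np.inf
            t2 = tmap[i2, j2] if 0 <= i2 < h and 0 <= j2 < w and flags[i2, j2] == _KNOWN else np.inf
            lo, hi = (t1, t2) if t1 <= t2 else (t2, t1)
            if np.isinf(lo):
                continue
            if np.isinf(hi) or hi - lo >= 1.0:
                cand = lo + 1.0
            else:
                s = lo + hi
                d = s * s - 2.0 * (lo * lo + hi * hi - 1.0)
                cand = (s + np.sqrt(d)) / 2.0 if d >= 0 else lo + 1.0
            best = min(best, cand)
        return best

    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    # seed the narrow band: masked pixels 4-adjacent to known ones
    for i, j in np.argwhere(mask):
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and flags[ni, nj] == _KNOWN:
                t = eikonal(i, j)
                if t < tmap[i, j]:
                    tmap[i, j] = t
                    flags[i, j] = _BAND
                    heapq.heappush(heap, (t, counter, i, j))
                    counter += 1
                break

    # precomputed neighborhood offsets sorted by distance
    r = cfg.radius
    base_offsets = _disk_offsets(r)

    def fill_pixel(i: int, j: int) -> None:
        # gradient of T at p from available values (unknown T treated as T(p))
        tp = tmap[i, j]
        gx = _t_diff(tmap, flags, i, j + 1, tp) - _t_diff(tmap, flags, i, j - 1, tp)
        gy = _t_diff(tmap, flags, i + 1, j, tp) - _t_diff(tmap, flags, i - 1, j, tp)
        gnorm = np.hypot(gx, gy)
        if gnorm > 0:
            gx, gy = gx / gnorm, gy / gnorm
        offsets = base_offsets
        while True:
            wsum = 0.0
            vsum = np.zeros(3)
            for di, dj, dist in offsets:
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or flags[ni, nj] != _KNOWN:
                    continue
                direction = abs(di * gy + dj * gx) / dist
                if direction < 1e-6:
                    direction = 1e-6
                dst = 1.0 / (dist * dist)
                lev = 1.0 / (1.0 + abs(tp - tmap[ni, nj]))
                wgt = direction * dst * lev
                wsum += wgt
                vsum += wgt * out[ni, nj]
            if wsum > 0:
                out[i, j] = vsum / wsum
                return
            # isolated pixel: enlarge the neighborhood until a known pixel appears
            offsets = _disk_offsets(int(offsets[-1][2]) + r)

    while heap:
        t, _, i, j = heapq.heappop(heap)
        if flags[i, j] != _BAND or t > tmap[i, j]:
            continue
        flags[i, j] = _KNOWN
        fill_pixel(i, j)
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and flags[ni, nj] != _KNOWN:
                tn = eikonal(ni, nj)
                if tn < tmap[ni, nj]:
                    tmap[ni, nj] = tn
                    flags[ni, nj] = _BAND
                    heapq.heappush(heap, (tn, counter, ni, nj))
                    counter += 1

    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _t_diff(tmap: np.ndarray, flags: np.ndarray, i: int, j: int, fallback: float) -> float:
    h, w = tmap.shape
    if 0 <= i < h and 0 <= j < w and np.isfinite(tmap[i, j]):
        return tmap[i, j]
    return fallback


def _disk_offsets(radius: int) -> list[tuple[int, int, float]]:
    out = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if di == 0 and dj == 0:
                continue
            d = np.hypot(di, dj)
            if d <= radius:
                out.append((di, dj, d))
    out.sort(key=lambda o: o[2])
    return out


def remove_hair(
    image: np.ndarray,
    cfg: InpaintConfig | None = None,
    se_size: int = DEFAULT_SE_SIZE,
    return_mask: bool = False,
):
    """Full hair-removal pipeline on an RGB image at its native resolution.

    Grayscale conversion, black top-hat with a cross element of ``se_size``,
    thresholding, and fast-marching inpainting of the detected pixels in the
    RGB image. Returns the inpainted image (and the hair mask if requested).
    """
    cfg = cfg or InpaintConfig()
    gray = to_grayscale(image)
    se = cross_element(se_size)
    tophat = black_tophat(gray, se)
    mask = hair_mask(tophat, cfg.threshold)
    if mask.all():  # pathological frame: nothing known, skip inpainting
        result = np.asarray(image).copy()
    else:
        result = inpaint_fmm(image, mask, cfg)
    if return_mask:
        return result, mask
    return result
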