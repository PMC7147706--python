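"""Synthetic dermoscopy-like images with exact ground truth.

Real dermoscopic archives (ISIC, PH2) cannot be redistributed with a code
package, so every downstream stage is exercised on generated frames that
reproduce the features the pipeline cares about: a skin-toned background, one
connected darker lesion with an irregular border and a pixel-exact mask, and
optional thin dark hair strokes with their own exact mask.

The lesion boundary is a radially perturbed ellipse: in the ellipse-normalized
frame the boundary radius is ``1 + border_irregularity * s(theta)`` where
``s`` is a smooth random harmonic series with ``max |s| <= 1``. The ellipse is
scaled so the enclosed continuous area matches a target fraction of the frame
drawn from ``lesion_area_fraction_range``. Base colors are fixed constants
jittered by Gaussian noise, so with the noise turned off the mask is exactly
the set of lesion-colored pixels.

Hairs are hard (non-anti-aliased) strokes along random quadratic Bezier arcs,
stamped with a disk of the chosen width, so the returned hair mask covers
precisely the altered pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SynthConfig", "generate_lesion_image", "add_hair_artifacts", "generate_dataset"]

SKIN_COLOR = np.array([205, 160, 140], dtype=np.float64)
LESION_BASE = np.array([130, 85, 70], dtype=np.float64)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator; same seed + config => identical bytes."""

    image_size: int = 256
    lesion_area_fraction_range: tuple[float, float] = (0.05, 0.40)
    lesion_darkening: float = 0.0  # extra uniform darkening added to the lesion base
    border_irregularity: float = 0.15
    n_hairs: int = 12
    hair_width_range: tuple[int, int] = (1, 3)
    hair_intensity: int = 40
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        lo, hi = self.lesion_area_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("lesion_area_fraction_range must be ordered and inside (0,1)")
        if self.border_irregularity < 0:
            raise ValueError("border_irregularity must be non-negative")
        if self.n_hairs < 0:
            raise ValueError("n_hairs must be non-negative")
        wlo, whi = self.hair_width_range
        if wlo < 1 or whi < wlo:
            raise ValueError("hair_width_range must be ordered positive integers")
        if not (0 <= self.hair_intensity <= 255):
            raise ValueError("hair_intensity must be an 8-bit value")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _boundary_noise(rng: np.random.Generator, n_harmonics: int = 5):
    """Smooth periodic function with max |s| normalized to 1."""
    ks = np.arange(2, 2 + n_harmonics)
    amps = rng.uniform(0.3, 1.0, size=n_harmonics) / ks  # smoother: damp high orders
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harmonics)
    probe = np.linspace(0.0, 2.0 * np.pi, 1024, endpoint=False)
    vals = np.sum(amps[:, None] * np.cos(ks[:, None] * probe[None] + phases[:, None]), axis=0)
    peak = np.max(np.abs(vals))

    def s(theta: np.ndarray) -> np.ndarray:
        v = np.sum(
            amps[:, None] * np.cos(ks[:, None] * theta[None] + phases[:, None]), axis=0
        )
        return v / peak if peak > 0 else v

    return s


def _lesion_mask(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    size = cfg.image_size
    lo, hi = cfg.lesion_area_fraction_range
    span = hi - lo
    # draw the target fraction slightly inside the band so rasterization error
    # (a boundary-length effect) cannot push the pixel count outside it
    margin = 0.05 * span
    for _ in range(16):
        frac = rng.uniform(lo + margin, hi - margin)
        aspect = rng.uniform(0.6, 1.0)
        angle = rng.uniform(0.0, np.pi)
        noise = _boundary_noise(rng) if cfg.border_irregularity > 0 else None

        # continuous area of r(theta) = rho(theta)*(1+irr*s(theta)) around an
        # ellipse with semi-axes (a, a*aspect): A = 0.5 * int rho^2 (1+irr*s)^2
        target_area = frac * size * size
        if noise is None:
            a = np.sqrt(target_area / (np.pi * aspect))
        else:
            th = np.linspace(0.0, 2.0 * np.pi, 2048, endpoint=False)
            sn = noise(th)
            denom = np.cos(th) ** 2 + (np.sin(th) / aspect) ** 2
            integrand = ((1.0 + cfg.border_irregularity * sn) ** 2) / denom
            unit_area = 0.5 * np.trapezoid(
                np.append(integrand, integrand[0]), dx=2.0 * np.pi / 2048
            )
            a = np.sqrt(target_area / unit_area)

        max_r = a * (1.0 + cfg.border_irregularity)
        half = size / 2.0
        slack = half - max_r - 2.0
        if slack < 0:  # lesion would clip the frame; redraw
            continue
        jitter = min(slack, 0.08 * size)
        cy = half + rng.uniform(-jitter, jitter)
        cx = half + rng.uniform(-jitter, jitter)

        yy, xx = np.mgrid[0:size, 0:size]
        dy = yy + 0.5 - cy
        dx = xx + 0.5 - cx
        ca, sa = np.cos(angle), np.sin(angle)
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        rho = np.sqrt((u / a) ** 2 + (v / (a * aspect)) ** 2)
        if noise is None:
            mask = rho <= 1.0
        else:
            theta = np.arctan2(v / aspect, u)
            mask = rho <= 1.0 + cfg.border_irregularity * noise(theta.ravel()).reshape(
                theta.shape
            )
        got = mask.sum() / (size * size)
        if lo <= got <= hi:
            return mask.astype(np.uint8)
    raise RuntimeError("could not draw a lesion inside the requested area range")


def generate_lesion_image(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """One skin-toned frame with a single darker lesion and its exact mask."""
    rng = np.random.default_rng(cfg.seed)
    mask = _lesion_mask(cfg, rng)
    size = cfg.image_size
    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = SKIN_COLOR
    lesion_color = np.clip(LESION_BASE - cfg.lesion_darkening, 0, 255)
    img[mask.astype(bool)] = lesion_color
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def _stamp_offsets(width: int) -> np.ndarray:
    r = width / 2.0
    span = int(np.ceil(r))
    offs = [
        (di, dj)
        for di in range(-span, span + 1)
        for dj in range(-span, span + 1)
        if di * di + dj * dj <= r * r
    ]
    return np.array(offs, dtype=np.int64)


def add_hair_artifacts(
    image: np.ndarray, cfg: SynthConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Overlay ``cfg.n_hairs`` dark curved strokes; return image + exact mask.

    Strokes are quadratic Bezier arcs spanning a good part of the frame, drawn
    hard (no anti-aliasing) with a constant dark intensity so the set of
    altered pixels is exactly the stamped disk union.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("add_hair_artifacts expects an H x W x 3 image")
    h, w = image.shape[:2]
    out = image.copy()
    hair_px = np.zeros((h, w), dtype=bool)
    if cfg.n_hairs == 0:
        return out, hair_px.astype(np.uint8)
    # independent stream so hair placement does not disturb lesion draws
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x4A1B]))
    for _ in range(cfg.n_hairs):
        p0 = rng.uniform([0, 0], [h, w])
        p2 = rng.uniform([0, 0], [h, w])
        while np.hypot(*(p2 - p0)) < 0.4 * min(h, w):
            p2 = rng.uniform([0, 0], [h, w])
        mid = (p0 + p2) / 2.0
        normal = np.array([-(p2 - p0)[1], (p2 - p0)[0]])
        normal /= np.hypot(*normal)
        p1 = mid + normal * rng.uniform(-0.25, 0.25) * np.hypot(*(p2 - p0))
        width = int(rng.integers(cfg.hair_width_range[0], cfg.hair_width_range[1] + 1))
        n_steps = int(4 * np.hypot(*(p2 - p0)))
        t = np.linspace(0.0, 1.0, max(n_steps, 8))
        curve = (
            (1 - t)[:, None] ** 2 * p0[None]
            + 2 * ((1 - t) * t)[:, None] * p1[None]
            + t[:, None] ** 2 * p2[None]
        )
        pts = np.unique(np.rint(curve).astype(np.int64), axis=0)
        offs = _stamp_offsets(width)
        stamped = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
        keep = (
            (stamped[:, 0] >= 0) & (stamped[:, 0] < h) & (stamped[:, 1] >= 0) & (stamped[:, 1] < w)
        )
        stamped = stamped[keep]
        hair_px[stamped[:, 0], stamped[:, 1]] = True
    out[hair_px] = cfg.hair_intensity
    return out, hair_px.astype(np.uint8)


def generate_dataset(
    n: int, cfg: SynthConfig, with_hair: bool | None = None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Generate ``n`` (image, lesion-mask) pairs, seeds derived from cfg.seed.

    ``with_hair`` overrides the hair toggle; by default hairs are added when
    ``cfg.n_hairs > 0``. Returned masks are the lesion ground truth (hair
    masks are internal to the generator).
    """
    images, masks = [], []
    add_hair = cfg.n_hairs > 0 if with_hair is None else with_hair
    root = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n)]
    for s in child_seeds:
        sub = replace(cfg, seed=s)
        img, mask = generate_lesion_image(sub)
        if add_hair:
            img, _ = add_hair_artifacts(img, sub)
        images.append(img)
        masks.append(mask)
    return images, masks
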