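"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by the most literal method available —
sliding-window min/max loops for grayscale morphology, concordant-pair
counting for AUC — and never call the implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def naive_dilate(image: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Grayscale dilation: windowed max over the footprint, edge replication."""
    r = se.shape[0] // 2
    padded = np.pad(image, r, mode="edge")
    out = np.empty_like(image)
    h, w = image.shape
    for i in range(h):
        for j in range(w):
            window = padded[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = window[se].max()
    return out


def naive_erode(image: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Grayscale erosion: windowed min over the footprint, edge replication."""
    r = se.shape[0] // 2
    padded = np.pad(image, r, mode="edge")
    out = np.empty_like(image)
    h, w = image.shape
    for i in range(h):
        for j in range(w):
            window = padded[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = window[se].min()
    return out


def naive_close(image: np.ndarray, se: np.ndarray) -> np.ndarray:
    return naive_erode(naive_dilate(image, se), se)


def naive_black_tophat(image: np.ndarray, se: np.ndarray) -> np.ndarray:
    return naive_close(image, se).astype(np.int64) - image.astype(np.int64)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the concordant-pair statistic (ties count one half)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-2) -> np.ndarray:
    """Central-difference gradient of scalar f wrt array x (float32-friendly)."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
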