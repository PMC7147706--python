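"""Segmentation quality metrics: Jaccard, Dice, pixel rates, and ROC/AUC.

Per-image metrics are computed from the pixel confusion counts of a predicted
binary mask against its ground truth; dataset aggregates are unweighted means
over images (the challenge convention). The ROC curve pools every pixel of
the dataset, sweeps each distinct predicted probability as a threshold, and
integrates by the trapezoidal rule, which equals the Mann-Whitney concordant-
pair statistic.

Two empty masks (a correct all-background prediction) score Jaccard and Dice
of 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "MetricsRecord",
    "RocCurve",
    "confusion",
    "jaccard",
    "dice",
    "sensitivity",
    "specificity",
    "pixel_accuracy",
    "metrics_record",
    "roc",
    "evaluate_dataset",
    "plot_roc",
]


@dataclass(frozen=True)
class MetricsRecord:
    jaccard: float
    dice: float
    sensitivity: float
    specificity: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "jaccard": self.jaccard,
            "dice": self.dice,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _check_shapes(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return pred > 0, truth > 0


def confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """Pixel counts (TP, FP, TN, FN); they always sum to the pixel total."""
    p, t = _check_shapes(pred, truth)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    tn = int(np.count_nonzero(~p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return tp, fp, tn, fn


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    tp, fp, _, fn = confusion(pred, truth)
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """2 |A&B| / (|A|+|B|); 1.0 when both masks are empty."""
    tp, fp, _, fn = confusion(pred, truth)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def sensitivity(pred: np.ndarray, truth: np.ndarray) -> float:
    tp, _, _, fn = confusion(pred, truth)
    return 1.0 if tp + fn == 0 else tp / (tp + fn)


def specificity(pred: np.ndarray, truth: np.ndarray) -> float:
    _, fp, tn, _ = confusion(pred, truth)
    return 1.0 if tn + fp == 0 else tn / (tn + fp)


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    tp, fp, tn, fn = confusion(pred, truth)
    return (tp + tn) / (tp + fp + tn + fn)


def metrics_record(pred: np.ndarray, truth: np.ndarray) -> MetricsRecord:
    tp, fp, tn, fn = confusion(pred, truth)
    union = tp + fp + fn
    return MetricsRecord(
        jaccard=1.0 if union == 0 else tp / union,
        dice=1.0 if union == 0 else 2 * tp / (2 * tp + fp + fn),
        sensitivity=1.0 if tp + fn == 0 else tp / (tp + fn),
        specificity=1.0 if tn + fp == 0 else tn / (tn + fp),
        accuracy=(tp + tn) / (tp + fp + tn + fn),
    )


def roc(
    probabilities: Sequence[np.ndarray], truths: Sequence[np.ndarray]
) -> RocCurve:
    """Pooled pixel-wise ROC over a dataset of probability maps.

    Every distinct score is swept as a threshold (equal scores grouped into a
    single step); AUC by the trapezoidal rule. Requires at least one positive
    and one negative pixel overall.
    """
    if len(probabilities) != len(truths) or len(truths) == 0:
        raise ValueError("probabilities and truths must be non-empty paired sequences")
    scores, labels = [], []
    for p, t in zip(probabilities, truths):
        p = np.asarray(p, dtype=np.float64)
        t = np.asarray(t)
        if p.shape != t.shape:
            raise ValueError("probability map and truth mask shapes differ")
        scores.append(p.ravel())
        labels.append((t > 0).ravel())
    y_score = np.concatenate(scores)
    y_true = np.concatenate(labels)
    if y_true.all() or not y_true.any():
        raise ValueError("ROC undefined: ground truth contains a single class")
    fpr, tpr, thr = _sk_roc_curve(y_true, y_score, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def evaluate_dataset(
    model,
    images: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    dehair: bool = False,
    threshold: float = 0.5,
    inpaint_config=None,
) -> tuple[list[MetricsRecord], MetricsRecord, RocCurve]:
    """Run the model over a dataset and score it against ground truth.

    Each image is optionally dehaired, resized/normalized, and segmented at
    ``threshold``; metrics are computed per image at the network resolution
    and averaged arithmetically. One pooled ROC covers all pixels. Toggling
    ``dehair`` on hair-free data should leave the scores essentially
    unchanged, which is the designed A/B use of this harness.
    """
    from .hair_removal import InpaintConfig, remove_hair
    from .preprocess import normalize, resize_pair

    if len(images) == 0 or len(images) != len(truths):
        raise ValueError("images and truths must be non-empty paired sequences")
    per_image: list[MetricsRecord] = []
    prob_maps: list[np.ndarray] = []
    net_truths: list[np.ndarray] = []
    for img, truth in zip(images, truths):
        if dehair:
            img = remove_hair(img, inpaint_config or InpaintConfig())
        rimg, rmask = resize_pair(img, truth)
        batch = normalize(rimg).pixels.transpose(2, 0, 1)[None]
        prob = model.forward(batch)[0]
        pred = (prob > threshold).astype(np.uint8)
        per_image.append(metrics_record(pred, rmask))
        prob_maps.append(prob)
        net_truths.append(rmask)
    agg = MetricsRecord(
        jaccard=float(np.mean([m.jaccard for m in per_image])),
        dice=float(np.mean([m.dice for m in per_image])),
        sensitivity=float(np.mean([m.sensitivity for m in per_image])),
        specificity=float(np.mean([m.specificity for m in per_image])),
        accuracy=float(np.mean([m.accuracy for m in per_image])),
    )
    curve = roc(prob_maps, net_truths)
    return per_image, agg, curve


def plot_roc(curve: RocCurve, path: str) -> None:
    """Save a ROC plot (matplotlib, headless backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(curve.fpr, curve.tpr, label=f"AUC = {curve.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("Pixel-wise ROC")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
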