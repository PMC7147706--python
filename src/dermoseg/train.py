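"""Training loop: binary cross-entropy, Adam, rotation augmentation,
learning-rate reduction and early stopping on a validation-loss plateau.

The recipe follows the segmentation network's published hyperparameters:
batch size 16, Adam at 1e-3, up to 100 epochs, binary cross-entropy loss, and
runtime rotation augmentation that triples the training set (each image plus
its 90- and 180-degree in-plane rotations, masks rotated identically). When
the validation loss fails to improve for ``patience`` epochs the learning
rate is multiplied once by ``lr_reduce_factor``; if no improvement follows
for another ``patience`` epochs, training stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .model import ResUNet
from .preprocess import TARGET_SIZE, normalize, resize_pair

__all__ = ["TrainConfig", "TrainHistory", "augment_rotations", "fit"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 10
    lr_reduce_factor: float = 0.1
    loss: str = "binary_crossentropy"
    optimizer: str = "adam"
    augment: bool = True
    seed: int = 0
    validation_fraction: float = 0.1
    min_delta: float = 1e-4  # smallest val-loss drop that counts as progress

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 < self.lr_reduce_factor < 1.0):
            raise ValueError("lr_reduce_factor must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.loss != "binary_crossentropy":
            raise ValueError("only binary_crossentropy loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    lr_schedule: list[tuple[int, float]] = field(default_factory=list)
    stop_epoch: int = 0
    train_indices: list[int] = field(default_factory=list)
    val_indices: list[int] = field(default_factory=list)


def augment_rotations(
    images: Sequence[np.ndarray], masks: Sequence[np.ndarray], seed: int = 0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Each pair plus its 90- and 180-degree rotations: 3n pairs out.

    Rotations are exact array rotations (no resampling), so mask foreground
    counts are preserved and pairing is maintained. ``seed`` is accepted for
    interface stability; the rotation set is deterministic.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must be paired")
    out_i: list[np.ndarray] = []
    out_m: list[np.ndarray] = []
    for img, msk in zip(images, masks):
        out_i.append(img)
        out_m.append(msk)
        for k in (1, 2):
            out_i.append(np.rot90(img, k=k, axes=(0, 1)).copy())
            out_m.append(np.rot90(msk, k=k, axes=(0, 1)).copy())
    return out_i, out_m


def _to_batch_arrays(
    images: Sequence[np.ndarray], masks: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for img, msk in zip(images, masks):
        rimg, rmsk = resize_pair(img, msk)
        xs.append(normalize(rimg).pixels.transpose(2, 0, 1))
        ys.append(rmsk[None].astype(np.float32))
    return np.stack(xs).astype(np.float32), np.stack(ys)


def fit(
    model: ResUNet,
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    cfg: TrainConfig,
    early_stopping: bool = True,
    verbose: bool = False,
) -> tuple[ResUNet, TrainHistory]:
    """Train the segmentation model on paired RGB images and binary masks.

    Images may be any size; they are resized/normalized internally. The
    validation split is carved off before augmentation so rotated copies of a
    validation image never leak into training. Returns the trained model and
    the epoch-by-epoch history.
    """
    if len(images) != len(masks) or len(images) == 0:
        raise ValueError("images and masks must be non-empty paired sequences")
    rng = np.random.default_rng(cfg.seed)
    n = len(images)
    order = rng.permutation(n)
    n_val = max(1, round(cfg.validation_fraction * n)) if n > 1 else 0
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training samples left after the validation split")

    train_imgs = [images[i] for i in train_idx]
    train_msks = [masks[i] for i in train_idx]
    if cfg.augment:
        train_imgs, train_msks = augment_rotations(train_imgs, train_msks, seed=cfg.seed)
    if len(train_imgs) < 2 * cfg.batch_size:
        raise ValueError(
            "need at least 2*batch_size training pairs after augmentation; "
            f"got {len(train_imgs)}"
        )

    x_train, y_train = _to_batch_arrays(train_imgs, train_msks)
    x_val, y_val = _to_batch_arrays(
        [images[i] for i in val_idx], [masks[i] for i in val_idx]
    ) if n_val else (None, None)

    params = model.parameters()
    opt = nn.Adam(params, lr=cfg.learning_rate)
    history = TrainHistory()
    history.lr_schedule.append((1, cfg.learning_rate))
    history.train_indices = [int(i) for i in train_idx]
    history.val_indices = [int(i) for i in val_idx]

    best_val = np.inf
    since_improve = 0
    reduced = False
    n_train = x_train.shape[0]

    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        perm = rng.permutation(n_train)
        losses, accs = [], []
        for start in range(0, n_train, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb = x_train[idx]
            yb = y_train[idx]
            logits = model.forward_logits(xb)
            loss = nn.bce_with_logits(logits, yb)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss_val}"
                )
            acc = float(((logits.data > 0.0) == (yb > 0.5)).mean())
            opt.zero_grad()
            loss.backward()  # releases activation buffers as it walks the graph
            opt.step()
            losses.append(loss_val)
            accs.append(acc)
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(float(np.mean(accs)))

        if x_val is not None:
            val_loss, val_acc = _evaluate_loss(model, x_val, y_val, cfg.batch_size)
        else:  # degenerate single-image dataset: monitor the training loss
            val_loss, val_acc = history.train_loss[-1], history.train_accuracy[-1]
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.stop_epoch = epoch
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {history.train_loss[-1]:.4f}  "
                f"acc {history.train_accuracy[-1]:.4f}  val_loss {val_loss:.4f}  "
                f"val_acc {val_acc:.4f}  lr {opt.lr:.2e}"
            )

        if not early_stopping:
            continue
        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                if not reduced:
                    opt.lr *= cfg.lr_reduce_factor
                    history.lr_schedule.append((epoch, opt.lr))
                    reduced = True
                    since_improve = 0
                else:
                    break
    _recalibrate_batchnorm(model, x_train, cfg.batch_size)
    model.eval()
    return model, history


def _recalibrate_batchnorm(model: ResUNet, x: np.ndarray, batch_size: int) -> None:
    """Replace EMA batchnorm statistics with population statistics.

    The exponential moving average lags badly on short runs with few batches
    per epoch; a final pass over the training inputs in training mode, plainly
    averaging batch statistics, gives inference-mode behavior that matches
    what the network saw while learning.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    for bn in bns:
        bn.start_stat_accumulation()
    model.train()
    try:
        for start in range(0, x.shape[0], batch_size):
            xb = x[start : start + batch_size]
            if xb.shape[0] >= 2:  # single-image batch statistics are degenerate
                model.forward_logits(xb)
    finally:
        for bn in bns:
            bn.finish_stat_accumulation()


def _evaluate_loss(
    model: ResUNet, x: np.ndarray, y: np.ndarray, batch_size: int
) -> tuple[float, float]:
    model.eval()
    losses, accs = [], []
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        yb = y[start : start + batch_size]
        logits = model.forward_logits(xb)
        loss = nn.bce_with_logits(logits, yb)
        losses.append(float(loss.data) * xb.shape[0])
        accs.append(float(((logits.data > 0.0) == (yb > 0.5)).mean()) * xb.shape[0])
    return float(np.sum(losses) / x.shape[0]), float(np.sum(accs) / x.shape[0])


def plot_history(history: TrainHistory, path: str) -> None:
    """Save loss/accuracy curves (matplotlib, headless backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = np.arange(1, len(history.train_loss) + 1)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].plot(epochs, history.train_loss, label="train")
    axes[0].plot(epochs, history.val_loss, label="validation")
    axes[0].set_xlabel("epoch")
    axes[0].set_ylabel("binary cross-entropy")
    axes[0].legend()
    axes[1].plot(epochs, history.train_accuracy, label="train")
    axes[1].plot(epochs, history.val_accuracy, label="validation")
    axes[1].set_xlabel("epoch")
    axes[1].set_ylabel("pixel accuracy")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
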