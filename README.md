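# dermoseg

Automatic delineation of skin-lesion boundaries in dermoscopic images.
Accurate lesion segmentation is the first step of computer-aided melanoma
screening: treatment decisions hinge on where the lesion ends, and manual
tracing is slow and inconsistent. Dermoscopic frames are also routinely
crossed by hair shafts that corrupt boundary detectors.

`dermoseg` implements a complete segmentation pipeline:

1. **Hair removal** — hairs are detected with a black top-hat filter
   (grayscale closing with a 17x17 cross structuring element minus the
   image, thresholded at 10) and filled by fast-marching inpainting, where
   each masked pixel is replaced by a weighted average of its already-known
   neighbors in front-propagation order.
2. **Res-Unet** — an encoder-decoder network: a ResNet-50 contracting path
   (bottleneck blocks, deepest feature 8x8x2048 for a 256x256 input) and a
   U-Net expansive path (five 2x2 up-convolutions, ten 3x3 convolutions,
   1x1 sigmoid head back to 256x256x1), with encoder features concatenated
   into the decoder at matching resolutions. The network runs on a compact
   numpy autodiff engine included in the package; a `width_multiplier`
   scales channel widths for CPU-scale experiments.
3. **Training** — pixel-wise binary cross-entropy, Adam (lr 1e-3), batch 16,
   up to 100 epochs, rotation augmentation (x3), learning-rate reduction and
   early stopping on a validation-loss plateau (patience 10).
4. **Evaluation** — Jaccard index `TP/(TP+FP+FN)`, Dice `2TP/(2TP+FP+FN)`
   (`DC = 2 JI/(1+JI)`), sensitivity, specificity, pixel accuracy, and a
   pooled pixel-wise ROC with trapezoidal AUC.
5. **Synthetic dermoscopy generator** — skin-toned frames with one irregular
   darker lesion (exact ground-truth mask) and optional hard-edged hair
   strokes (exact hair mask), so the entire pipeline is developed and tested
   without clinical data.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

Generate synthetic training and test sets, train a quarter-width model for 8
epochs (~6 minutes on one CPU core), and score it on the held-out images:

```bash
dermoseg synth --n 96 --out data/ --seed 1 --hairs 0
dermoseg synth --n 16 --out test/ --seed 2 --hairs 0
printf 'augment: false\n' > cfg.yaml
dermoseg train --data data/ --config cfg.yaml --out model.npz --seed 42 --width 0.25 --epochs 8
dermoseg eval --model model.npz --data test/ --out metrics.json --no-dehair
```

The training log prints one line per epoch (loss is pixel-wise binary
cross-entropy, accuracy the fraction of pixels correct at threshold 0.5):

```
epoch   1  loss 0.4905  acc 0.7893  val_loss 0.9601  val_acc 0.6903  lr 1.00e-03
epoch   2  loss 0.3943  acc 0.8341  val_loss 0.2518  val_acc 0.9661  lr 1.00e-03
...
epoch   8  loss 0.2870  acc 0.9347  val_loss 0.2264  val_acc 0.9929  lr 1.00e-03
stopped at epoch 8; checkpoint: model.npz
```

and evaluation on the 16 held-out images reports

```
jaccard 0.9302  dice 0.9638  auc 1.0000
```

meaning the predicted masks overlap the ground truth by ~93% intersection
over union (Dice ~0.96) and the pooled pixel probabilities separate lesion
from skin essentially perfectly. `metrics.json` holds the same numbers per
image and aggregated. Convergence onset varies by a few epochs across seeds
at this scale; short runs benefit from a fixed `--seed`. Hair removal is
available standalone:

```bash
dermoseg dehair data/img_0000.png --out clean.png --save-mask hair.png
```

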