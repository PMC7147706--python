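"""Res-Unet segmentation network: ResNet-50 encoder, U-Net decoder.

The encoder is the canonical ResNet-50 contracting path (7x7/64 stride-2 stem,
3x3 stride-2 max pool, then four bottleneck stages with inner widths
64/128/256/512, output widths 256/512/1024/2048 and repeats 3/4/6/3). With a
256x256 input the stage outputs have spatial sides 64, 32, 16 and 8, the
deepest feature map being 8x8x2048.

The decoder alternates five 2x2 stride-2 transposed convolutions (U1-U5) with
ten 3x3 convolutions (D1-D10, output widths 256,256,128,128,64,64,32,32,16,16)
and ends in a 1x1 convolution to a single channel passed through a sigmoid,
restoring a 256x256x1 probability map. Encoder features at 16x16 (1024 ch),
32x32 (512 ch), 64x64 (256 ch) and 128x128 (64 ch, post-stem) are channel-
concatenated to the upsampled tensor before D1, D3, D5 and D7; there is no
same-resolution feature before the stem, so U5/D9 receives no skip.

Every convolution is followed by batch normalization and ReLU except the 1x1
head. A ``width_multiplier`` scales all channel counts for desk-scale
experiments without changing any spatial dimension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from . import nn
from .preprocess import TARGET_SIZE, normalize, resize_pair

__all__ = [
    "EncoderSpec",
    "DecoderSpec",
    "ResUNet",
    "build_resunet",
    "predict_mask",
    "save_model",
    "load_model",
]

# Foreground prior used to initialize the head bias: lesions typically cover a
# minority of the frame, and log(p/(1-p)) at p=0.2 speeds up early convergence
# of the binary cross-entropy.
_HEAD_BIAS_PRIOR = -1.386


@dataclass(frozen=True)
class EncoderSpec:
    """Structural description of the ResNet-50 contracting path."""

    stem_kernel: int = 7
    stem_filters: int = 64
    stem_stride: int = 2
    pool_kernel: int = 3
    pool_stride: int = 2
    inner_filters: tuple[int, ...] = (64, 128, 256, 512)
    output_filters: tuple[int, ...] = (256, 512, 1024, 2048)
    repeats: tuple[int, ...] = (3, 4, 6, 3)

    def stage_sides(self, input_side: int = TARGET_SIZE) -> tuple[int, ...]:
        side = input_side // self.stem_stride // self.pool_stride
        sides = [side]
        for _ in range(len(self.repeats) - 1):
            side //= 2
            sides.append(side)
        return tuple(sides)


@dataclass(frozen=True)
class DecoderSpec:
    """Structural description of the U-Net expansive path."""

    up_kernel: int = 2
    conv_kernel: int = 3
    conv_filters: tuple[int, ...] = (256, 256, 128, 128, 64, 64, 32, 32, 16, 16)
    head_kernel: int = 1
    head_filters: int = 1

    @property
    def n_convs(self) -> int:
        return len(self.conv_filters)


#: encoder stage -> decoder conv the skip feeds (channel concatenation)
SKIP_WIRING: tuple[tuple[str, str], ...] = (
    ("conv4", "D1"),
    ("conv3", "D3"),
    ("conv2", "D5"),
    ("conv1", "D7"),
)


def _scaled(channels: int, multiplier: float) -> int:
    return max(1, round(channels * multiplier))


class _ConvBNReLU(nn.Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, padding=pad, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.relu(self.bn(self.conv(x)), in_place=True)


class _Bottleneck(nn.Module):
    """1x1 reduce -> 3x3 -> 1x1 restore, with identity or projection shortcut."""

    def __init__(self, cin: int, inner: int, cout: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, inner, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(inner)
        self.conv2 = nn.Conv2d(inner, inner, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(inner)
        self.conv3 = nn.Conv2d(inner, cout, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(cout)
        else:
            self.proj = None
            self.proj_bn = None

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        out = nn.relu(self.bn1(self.conv1(x)), in_place=True)
        out = nn.relu(self.bn2(self.conv2(out)), in_place=True)
        out = self.bn3(self.conv3(out))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return nn.relu(nn.add(out, shortcut), in_place=True)


class _Encoder(nn.Module):
    def __init__(self, spec: EncoderSpec, multiplier: float, rng):
        super().__init__()
        self.spec = spec
        w = multiplier
        stem_c = _scaled(spec.stem_filters, w)
        self.stem = _ConvBNReLU(3, stem_c, spec.stem_kernel, spec.stem_stride, spec.stem_kernel // 2, rng)
        self.pool = nn.MaxPool2d(spec.pool_kernel, spec.pool_stride, padding=1)
        self.stages: list[list[_Bottleneck]] = []
        cin = stem_c
        for si, (inner, cout, reps) in enumerate(
            zip(spec.inner_filters, spec.output_filters, spec.repeats)
        ):
            blocks = []
            for b in range(reps):
                stride = 2 if (b == 0 and si > 0) else 1
                blocks.append(_Bottleneck(cin, _scaled(inner, w), _scaled(cout, w), stride, rng))
                cin = _scaled(cout, w)
            self.stages.append(blocks)

    def __call__(self, x: nn.Tensor) -> dict[str, nn.Tensor]:
        feats: dict[str, nn.Tensor] = {}
        t = self.stem(x)
        feats["conv1"] = t
        t = self.pool(t)
        feats["pool"] = t
        for si, blocks in enumerate(self.stages):
            for block in blocks:
                t = block(t)
            feats[f"conv{si + 2}"] = t
        return feats


class _Decoder(nn.Module):
    def __init__(
        self,
        spec: DecoderSpec,
        encoder_spec: EncoderSpec,
        multiplier: float,
        rng,
    ):
        super().__init__()
        self.spec = spec
        w = multiplier
        enc_out = [_scaled(c, w) for c in encoder_spec.output_filters]
        stem_c = _scaled(encoder_spec.stem_filters, w)
        conv_c = [_scaled(c, w) for c in spec.conv_filters]
        # skip channel widths seen before D1, D3, D5, D7 (deepest first)
        skips = [enc_out[2], enc_out[1], enc_out[0], stem_c, 0]
        self.ups: list[nn.ConvTranspose2d] = []
        self.convs: list[_ConvBNReLU] = []
        cin = enc_out[3]
        for level in range(5):
            self.ups.append(nn.ConvTranspose2d(cin, cin, rng=rng))
            c1, c2 = conv_c[2 * level], conv_c[2 * level + 1]
            self.convs.append(_ConvBNReLU(cin + skips[level], c1, 3, 1, 1, rng))
            self.convs.append(_ConvBNReLU(c1, c2, 3, 1, 1, rng))
            cin = c2
        self.head = nn.Conv2d(cin, spec.head_filters, 1, rng=rng)
        self.head.bias.data[:] = _HEAD_BIAS_PRIOR

    def __call__(self, feats: Mapping[str, nn.Tensor]) -> nn.Tensor:
        skip_order = ["conv4", "conv3", "conv2", "conv1", None]
        t = feats["conv5"]
        for level in range(5):
            t = self.ups[level](t)
            skip = skip_order[level]
            if skip is not None:
                t = nn.concat(t, feats[skip])
            t = self.convs[2 * level](t)
            t = self.convs[2 * level + 1](t)
        return self.head(t)  # logits


@dataclass
class ShapeRecord:
    name: str
    height: int
    width: int
    channels: int


class ResUNet(nn.Module):
    """The full encoder-decoder; ``forward`` maps NCHW inputs to logits."""

    def __init__(
        self,
        width_multiplier: float = 1.0,
        seed: int | None = None,
        encoder_spec: EncoderSpec = EncoderSpec(),
        decoder_spec: DecoderSpec = DecoderSpec(),
    ):
        super().__init__()
        if width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        self.width_multiplier = width_multiplier
        self.seed = seed
        self.encoder_spec = encoder_spec
        self.decoder_spec = decoder_spec
        self.skip_wiring = SKIP_WIRING
        rng = np.random.default_rng(seed)
        self.encoder = _Encoder(encoder_spec, width_multiplier, rng)
        self.decoder = _Decoder(decoder_spec, encoder_spec, width_multiplier, rng)

    # -- core passes --------------------------------------------------------

    def forward_logits(self, x: np.ndarray | nn.Tensor) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.ascontiguousarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N,3,H,W) input, got {x.shape}")
        if x.shape[2] != TARGET_SIZE or x.shape[3] != TARGET_SIZE:
            raise ValueError(
                f"network input must be {TARGET_SIZE}x{TARGET_SIZE}, got {x.shape[2]}x{x.shape[3]}"
            )
        feats = self.encoder(x)
        return self.decoder(feats)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Inference: probability maps (N, H, W) in [0, 1]."""
        was_training = self.training
        self.eval()
        try:
            probs = nn.sigmoid(self.forward_logits(x)).data[:, 0]
        finally:
            if was_training:
                self.train()
        return probs

    # -- introspection ------------------------------------------------------

    def shape_walk(self) -> list[ShapeRecord]:
        """Run a 1-image forward pass and record every named feature shape."""
        was_training = self.training
        self.eval()
        try:
            x = nn.Tensor(np.zeros((1, 3, TARGET_SIZE, TARGET_SIZE), dtype=np.float32))
            feats = self.encoder(x)
            records = []
            for name in ("conv1", "pool", "conv2", "conv3", "conv4", "conv5"):
                _, c, h, w = feats[name].shape
                records.append(ShapeRecord(name, h, w, c))
            # mirror the decoder pass, logging U/D/head outputs
            skip_order = ["conv4", "conv3", "conv2", "conv1", None]
            t = feats["conv5"]
            d = self.decoder
            for level in range(5):
                t = d.ups[level](t)
                _, c, h, w = t.shape
                records.append(ShapeRecord(f"U{level + 1}", h, w, c))
                if skip_order[level] is not None:
                    t = nn.concat(t, feats[skip_order[level]])
                for k in range(2):
                    t = d.convs[2 * level + k](t)
                    _, c, h, w = t.shape
                    records.append(ShapeRecord(f"D{2 * level + k + 1}", h, w, c))
            t = d.head(t)
            _, c, h, w = t.shape
            records.append(ShapeRecord("output", h, w, c))
            return records
        finally:
            if was_training:
                self.train()


def build_resunet(
    width_multiplier: float = 1.0,
    pretrained_encoder: Mapping[str, np.ndarray] | None = None,
    seed: int | None = 0,
) -> ResUNet:
    """Construct a Res-Unet; optionally load externally supplied encoder weights.

    Parameters
    ----------
    width_multiplier:
        Scales every channel count in the layer tables. 1.0 reproduces the
        full network; 0.25 is convenient for CPU-scale training runs.
    pretrained_encoder:
        Mapping of encoder parameter names (as in ``named_parameters`` under
        ``encoder.``) to arrays. Shapes must match exactly.
    seed:
        Seed for He-normal weight initialization.
    """
    model = ResUNet(width_multiplier=width_multiplier, seed=seed)
    if pretrained_encoder is not None:
        named = dict(model.encoder.named_parameters())
        for key, value in pretrained_encoder.items():
            name = key[len("encoder.") :] if key.startswith("encoder.") else key
            if name not in named:
                raise KeyError(f"unknown encoder parameter {key!r}")
            arr = np.asarray(value, dtype=np.float32)
            if arr.shape != named[name].shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: expected {named[name].shape}, got {arr.shape}"
                )
            named[name].data = np.ascontiguousarray(arr)
    return model


def predict_mask(
    model: ResUNet,
    image: np.ndarray,
    threshold: float = 0.5,
    dehair: bool = False,
    restore_size: bool = True,
    inpaint_config=None,
) -> np.ndarray:
    """Segment one RGB image of arbitrary size into a binary lesion mask.

    The image is optionally passed through hair removal, then resized to the
    network resolution, normalized, and pushed through the model. Foreground
    is where the probability strictly exceeds ``threshold``.
    """
    from .hair_removal import InpaintConfig, remove_hair

    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("predict_mask expects an H x W x 3 RGB image")
    orig_h, orig_w = img.shape[:2]
    if dehair:
        img = remove_hair(img, inpaint_config or InpaintConfig())
    resized, _ = resize_pair(img, None)
    norm = normalize(resized)
    batch = norm.pixels.transpose(2, 0, 1)[None]
    prob = model.forward(batch)[0]
    mask = (prob > threshold).astype(np.uint8)
    if restore_size and (orig_h, orig_w) != mask.shape:
        from skimage.transform import resize as _sk_resize

        mask = (
            _sk_resize(mask.astype(float), (orig_h, orig_w), order=0, preserve_range=True) > 0.5
        ).astype(np.uint8)
    return mask


# ---------------------------------------------------------------------------
# serialization: npz of parameters + JSON sidecar describing the architecture

def save_model(model: ResUNet, path: str | Path) -> None:
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for name, p in model.named_parameters():
        arrays[name] = p.data
    for module, mname in _named_modules(model):
        if isinstance(module, nn.BatchNorm2d):
            arrays[f"{mname}.running_mean"] = module.running_mean
            arrays[f"{mname}.running_var"] = module.running_var
    with open(path, "wb") as fh:  # exact filename, no implicit .npz suffix
        np.savez(fh, **arrays)
    sidecar = {
        "format": "dermoseg-resunet",
        "width_multiplier": model.width_multiplier,
        "seed": model.seed,
        "skip_wiring": [list(pair) for pair in model.skip_wiring],
        "parameter_count": model.parameter_count(),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> ResUNet:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    model = ResUNet(width_multiplier=sidecar["width_multiplier"], seed=sidecar.get("seed"))
    with np.load(path) as data:
        named = dict(model.named_parameters())
        for name, p in named.items():
            p.data = np.ascontiguousarray(data[name].astype(np.float32))
        for module, mname in _named_modules(model):
            if isinstance(module, nn.BatchNorm2d):
                module.running_mean = data[f"{mname}.running_mean"].astype(np.float32)
                module.running_var = data[f"{mname}.running_var"].astype(np.float32)
    return model


def _named_modules(root: nn.Module, prefix: str = "") -> list[tuple[nn.Module, str]]:
    out: list[tuple[nn.Module, str]] = []
    for k, v in root.__dict__.items():
        for name, child in nn.Module._children(v, f"{prefix}{k}"):
            out.append((child, name))
            out.extend(_named_modules(child, prefix=name + "."))
    return out
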