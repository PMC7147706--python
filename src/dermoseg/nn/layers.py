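"""Neural-network layers on top of the :mod:`dermoseg.nn.autograd` tape.

Convolutions use im2col plus a single sgemm per image; the column matrix is
recomputed during the backward pass instead of cached, trading ~10% extra
arithmetic for a much smaller activation memory footprint (important when
training 256x256 inputs on a CPU-only host).

Tensor layout is NCHW throughout.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, accumulate_grad

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "MaxPool2d",
    "relu",
    "sigmoid",
    "add",
    "concat",
    "bce_with_logits",
]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.ascontiguousarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    @staticmethod
    def _children(value, name: str):
        """Yield (name, Module) pairs from attributes, lists, nested lists."""
        if isinstance(value, Module):
            yield name, value
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._children(item, f"{name}.{i}")

    def modules(self) -> list["Module"]:
        found: list[Module] = [self]
        for k, v in self.__dict__.items():
            for _, child in Module._children(v, k):
                found.extend(child.modules())
        return found

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((name, v))
            else:
                for child_name, child in Module._children(v, name):
                    out.extend(child.named_parameters(prefix=child_name + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))


# ---------------------------------------------------------------------------
# im2col / col2im

def im2col(xp: np.ndarray, kh: int, kw: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """Rearrange padded input (N,C,Hp,Wp) into columns (N, C*kh*kw, oh*ow)."""
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, kh * kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            # direct 4-D assignment: one strided copy, no intermediate reshape
            cols[:, :, i * kw + j] = xp[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ]
    return cols.reshape(n, c * kh * kw, oh * ow)


def col2im(
    dcols: np.ndarray,
    xp_shape: tuple[int, int, int, int],
    kh: int,
    kw: int,
    stride: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    """Scatter-add columns back onto the padded input shape (adjoint of im2col)."""
    n, c, _, _ = xp_shape
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    d = dcols.reshape(n, c, kh * kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, i * kw + j
            ]
    return dxp


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """2-D convolution (cross-correlation), square kernel, symmetric padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def __call__(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        oh, ow = self.out_size(h, w)
        w2 = self.weight.data.reshape(self.out_channels, -1)

        if k == 1:
            xs = x.data[:, :, ::s, ::s] if s > 1 else x.data
            y = np.matmul(w2, xs.reshape(n, c, oh * ow))
        else:
            xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="constant") if p else x.data
            cols = im2col(xp, k, k, s, oh, ow)
            y = np.matmul(w2, cols)
            # columns are ~k*k times the input activation: recompute them in
            # backward instead of keeping them alive across the whole graph
            del cols
        if self.bias is not None:
            y += self.bias.data[:, None]
        y = y.reshape(n, self.out_channels, oh, ow)

        def backward(dy: np.ndarray) -> None:
            dyf = dy.reshape(n, self.out_channels, oh * ow)
            if self.bias is not None:
                accumulate_grad(self.bias, dyf.sum(axis=(0, 2)))
            if k == 1:
                xs_b = x.data[:, :, ::s, ::s] if s > 1 else x.data
                xf = xs_b.reshape(n, c, oh * ow)
                dw = np.matmul(dyf, xf.transpose(0, 2, 1)).sum(axis=0)
                accumulate_grad(self.weight, dw.reshape(self.weight.shape))
                if x.needs_grad():
                    dxs = np.matmul(w2.T, dyf).reshape(n, c, oh, ow)
                    if s > 1:
                        dx = np.zeros_like(x.data)
                        dx[:, :, ::s, ::s] = dxs
                    else:
                        dx = dxs
                    accumulate_grad(x, dx, own=True)
            else:
                xp_b = (
                    np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="constant")
                    if p
                    else x.data
                )
                cols_b = im2col(xp_b, k, k, s, oh, ow)
                dw = np.matmul(dyf, cols_b.transpose(0, 2, 1)).sum(axis=0)
                accumulate_grad(self.weight, dw.reshape(self.weight.shape))
                if x.needs_grad():
                    dcols = np.matmul(w2.T, dyf)
                    dxp = col2im(
                        dcols, (n, c, h + 2 * p, w + 2 * p), k, k, s, oh, ow
                    )
                    dx = dxp[:, :, p : p + h, p : p + w] if p else dxp
                    accumulate_grad(x, dx, own=True)

        return Tensor(y, parents=(x,), backward_fn=backward)


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution (the U-Net 'up-conv')."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = 2
        self.stride = 2
        self.weight = Parameter(_he_normal(rng, (in_channels, out_channels, 2, 2), in_channels))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        xf = x.data.reshape(n, c, h * w)
        y = np.empty((n, self.out_channels, 2 * h, 2 * w), dtype=np.float32)
        for i in range(2):
            for j in range(2):
                wij = self.weight.data[:, :, i, j]  # (Cin, Cout)
                y[:, :, i::2, j::2] = np.matmul(wij.T, xf).reshape(n, self.out_channels, h, w)
        y += self.bias.data[None, :, None, None]

        def backward(dy: np.ndarray) -> None:
            accumulate_grad(self.bias, dy.sum(axis=(0, 2, 3)))
            dx = np.zeros_like(x.data) if x.needs_grad() else None
            dw = np.zeros_like(self.weight.data)
            for i in range(2):
                for j in range(2):
                    dyij = np.ascontiguousarray(dy[:, :, i::2, j::2]).reshape(
                        n, self.out_channels, h * w
                    )
                    dw[:, :, i, j] = np.matmul(xf, dyij.transpose(0, 2, 1)).sum(axis=0)
                    if dx is not None:
                        dx += np.matmul(self.weight.data[:, :, i, j], dyij).reshape(n, c, h, w)
            accumulate_grad(self.weight, dw, own=True)
            if dx is not None:
                accumulate_grad(x, dx, own=True)

        return Tensor(y, parents=(x,), backward_fn=backward)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) with running statistics for inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._stat_acc: list | None = None

    def start_stat_accumulation(self) -> None:
        """Begin replacing the EMA with population statistics.

        The population variance is E[batch var] + Var(batch means) (law of
        total variance); dropping the second term systematically
        underestimates spread for channels whose mean drifts between batches
        and makes inference-mode outputs explode by 1/sqrt(eps).
        """
        self._stat_acc = [
            np.zeros(self.channels, dtype=np.float64),  # sum of batch means
            np.zeros(self.channels, dtype=np.float64),  # sum of batch vars
            np.zeros(self.channels, dtype=np.float64),  # sum of squared means
            0,
        ]

    def finish_stat_accumulation(self) -> None:
        acc = self._stat_acc
        if acc is not None and acc[3] > 0:
            n = acc[3]
            mean = acc[0] / n
            var = acc[1] / n + np.maximum(acc[2] / n - mean**2, 0.0)
            self.running_mean = mean.astype(np.float32)
            self.running_var = var.astype(np.float32)
        self._stat_acc = None

    def __call__(self, x: Tensor) -> Tensor:
        xd = x.data
        n, c, h, w = xd.shape
        if self.training:
            m = n * h * w
            mean = xd.mean(axis=(0, 2, 3), dtype=np.float32)
            var = xd.var(axis=(0, 2, 3), dtype=np.float32)
            if self._stat_acc is not None:
                self._stat_acc[0] += mean
                self._stat_acc[1] += var
                self._stat_acc[2] += mean.astype(np.float64) ** 2
                self._stat_acc[3] += 1
            else:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
            invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            scale = self.gamma.data * invstd
            shift = self.beta.data - mean * scale
            y = xd * scale[None, :, None, None] + shift[None, :, None, None]

            def backward(dy: np.ndarray) -> None:
                # xhat recomputed from the stored input: trades one multiply-add
                # per element for not holding an extra activation-sized array
                xhat = (xd - mean[None, :, None, None]) * invstd[None, :, None, None]
                dgamma = (dy * xhat).sum(axis=(0, 2, 3))
                dbeta = dy.sum(axis=(0, 2, 3))
                accumulate_grad(self.gamma, dgamma)
                accumulate_grad(self.beta, dbeta)
                if x.needs_grad():
                    g = self.gamma.data * invstd
                    dx = (
                        dy
                        - (dbeta / m)[None, :, None, None]
                        - xhat * (dgamma / m)[None, :, None, None]
                    ) * g[None, :, None, None]
                    accumulate_grad(x, dx, own=True)

            return Tensor(y, parents=(x,), backward_fn=backward)

        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - self.running_mean * scale
        y = xd * scale[None, :, None, None] + shift[None, :, None, None]

        def backward_eval(dy: np.ndarray) -> None:
            accumulate_grad(self.beta, dy.sum(axis=(0, 2, 3)))
            accumulate_grad(
                self.gamma,
                (
                    dy
                    * (xd - self.running_mean[None, :, None, None])
                    / np.sqrt(self.running_var + self.eps)[None, :, None, None]
                ).sum(axis=(0, 2, 3)),
            )
            if x.needs_grad():
                accumulate_grad(x, dy * scale[None, :, None, None], own=True)

        return Tensor(y, parents=(x,), backward_fn=backward_eval)


class MaxPool2d(Module):
    """Max pooling with -inf padding (ResNet stem uses 3x3, stride 2, pad 1)."""

    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = x.shape
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(
            x.data,
            ((0, 0), (0, 0), (p, p), (p, p)),
            mode="constant",
            constant_values=-np.inf,
        )
        cols = im2col(xp, k, k, s, oh, ow).reshape(n, c, k * k, oh * ow)
        idx = cols.argmax(axis=2)
        y = np.take_along_axis(cols, idx[:, :, None, :], axis=2)[:, :, 0, :].reshape(n, c, oh, ow)

        def backward(dy: np.ndarray) -> None:
            if not x.needs_grad():
                return
            dcols = np.zeros((n, c, k * k, oh * ow), dtype=dy.dtype)
            np.put_along_axis(dcols, idx[:, :, None, :], dy.reshape(n, c, 1, oh * ow), axis=2)
            dxp = col2im(dcols.reshape(n, c * k * k, oh * ow), xp.shape, k, k, s, oh, ow)
            accumulate_grad(x, dxp[:, :, p : p + h, p : p + w], own=True)

        return Tensor(y, parents=(x,), backward_fn=backward)


# ---------------------------------------------------------------------------
# functional ops

def relu(x: Tensor, in_place: bool = False) -> Tensor:
    """Rectifier. ``in_place`` overwrites the input buffer — only safe when no
    other graph node reads ``x.data`` afterwards (e.g. right after a BN)."""
    y = np.maximum(x.data, 0.0, out=x.data if in_place else None)

    def backward(dy: np.ndarray) -> None:
        if x.needs_grad():
            accumulate_grad(x, np.where(y > 0.0, dy, 0.0), own=True)

    return Tensor(y, parents=(x,), backward_fn=backward)


def sigmoid(x: Tensor) -> Tensor:
    z = x.data
    y = np.empty_like(z)
    pos = z >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    y[~pos] = ez / (1.0 + ez)

    def backward(dy: np.ndarray) -> None:
        if x.needs_grad():
            accumulate_grad(x, dy * y * (1.0 - y), own=True)

    return Tensor(y, parents=(x,), backward_fn=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data

    def backward(dy: np.ndarray) -> None:
        # both parents may alias dy: consumers-first ordering makes it safe
        accumulate_grad(a, dy, own=True)
        accumulate_grad(b, dy, own=True)

    return Tensor(y, parents=(a, b), backward_fn=backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Channel-wise concatenation (axis 1)."""
    ca = a.shape[1]
    y = np.concatenate([a.data, b.data], axis=1)

    def backward(dy: np.ndarray) -> None:
        accumulate_grad(a, dy[:, :ca], own=True)
        accumulate_grad(b, dy[:, ca:], own=True)

    return Tensor(y, parents=(a, b), backward_fn=backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable in the logit domain."""
    z = logits.data
    t = targets
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    mean = np.asarray(loss.mean(), dtype=np.float32)

    def backward(dmean: np.ndarray) -> None:
        if logits.needs_grad():
            s = np.empty_like(z)
            pos = z >= 0
            s[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
            ez = np.exp(z[~pos])
            s[~pos] = ez / (1.0 + ez)
            accumulate_grad(logits, dmean * (s - t) / z.size, own=True)

    return Tensor(mean, parents=(logits,), backward_fn=backward)
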