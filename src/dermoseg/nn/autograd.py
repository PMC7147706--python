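"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and a
backward closure. Operations build a DAG; ``Tensor.backward()`` topologically
sorts it and propagates gradients. Only the handful of operations a
convolutional encoder-decoder needs are provided — this is deliberately a
micro-framework, not a general one.

All floating-point work is done in float32: convolution cost is dominated by
BLAS sgemm calls, which on a single CPU core are roughly twice as fast as
double precision.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["Tensor", "accumulate_grad"]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "parents", "backward_fn")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self.parents = parents
        self.backward_fn = backward_fn

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def needs_grad(self) -> bool:
        return self.requires_grad or bool(self.parents)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() must be called on a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are a few hundred nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)
            # free intermediate gradients and closures early so activation
            # buffers die as soon as the pass moves past them
            node.backward_fn = None
            if not node.requires_grad:
                node.grad = None
                node.parents = ()
                node.data = None  # type: ignore[assignment]

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        flag = "param" if self.requires_grad else ("node" if self.parents else "leaf")
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, {flag})"


def accumulate_grad(t: Tensor, g: np.ndarray, own: bool = False) -> None:
    """Add ``g`` into ``t.grad`` if ``t`` participates in differentiation.

    ``own=True`` lets the tensor take the array without copying; callers set
    it when ``g`` is freshly allocated (or aliases memory whose other readers
    have already been processed — backward runs consumers-first, so a buffer
    handed to a parent is never read again through the node that produced it).
    """
    if not t.needs_grad():
        return
    if t.grad is None:
        t.grad = g if own and isinstance(g, np.ndarray) else np.array(g, copy=True)
    else:
        t.grad += g

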