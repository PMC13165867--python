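"""Minimal reverse-mode autodiff on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and remembers how it was produced so
that :meth:`Tensor.backward` can push gradients to every upstream
:class:`Parameter`.  Only the operations the segmentation models need are
implemented (see :mod:`imau_seg.nn.ops`); each op registers a single closure
rather than composing many primitive nodes, which keeps graphs small and
CPU-friendly.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "Parameter", "accumulate_grad"]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        parents: Iterable["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ) -> None:
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    # -- conveniences -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate ``grad`` (default: ones) through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, self.dtype)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data: np.ndarray) -> None:
        super().__init__(np.ascontiguousarray(data), requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None


def accumulate_grad(t: Tensor, g: np.ndarray) -> None:
    """Add ``g`` into ``t.grad`` if ``t`` participates in the graph."""
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(t.dtype, copy=True)
    else:
        t.grad += g
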