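"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape.  Calling :meth:`Tensor.backward` on a scalar result walks the
tape in reverse topological order and accumulates vector-Jacobian products
into ``.grad`` of every tensor with ``requires_grad=True``.

Only the operations needed by the reconstruction pipeline are implemented:
elementwise arithmetic with broadcasting, matmul, ``sin``, ``abs``, slicing,
reductions, and a :func:`custom` hook through which the numba kernels
(projector, hash encoder, B-spline interpolant) inject their own VJPs.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "custom", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._vjp: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _from_op(data, parents, vjp) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._from_op(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor._from_op(
            self.data - other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(-g, other.data.shape)),
        )

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._from_op(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("division by a Tensor is not supported")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        return Tensor._from_op(
            self.data @ other.data,
            (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g),
        )

    def __getitem__(self, idx):
        def vjp(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._from_op(self.data[idx], (self,), vjp)

    # -- elementwise functions --------------------------------------------
    def sin(self):
        return Tensor._from_op(np.sin(self.data), (self,), lambda g: (g * np.cos(self.data),))

    def abs(self):
        return Tensor._from_op(np.abs(self.data), (self,), lambda g: (g * np.sign(self.data),))

    def square(self):
        return self * self

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._from_op(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def sum(self, axis=None):
        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._from_op(self.data.sum(axis=axis), (self,), vjp)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- backward ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order: graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
            if node is self and node.grad is None:
                # retain the seed on the output for inspection
                node.grad = np.asarray(grad, dtype=self.data.dtype)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def linear_sine(x: Tensor, W: Tensor, b: Tensor, omega: float | None) -> Tensor:
    """Fused ``sin(omega * (x @ W + b))`` (or plain affine if omega is None).

    One tape node instead of four; the backward pass recomputes the cosine
    from the stored pre-activation.
    """
    z = x.data @ W.data + b.data
    out = z if omega is None else np.sin(omega * z)

    def vjp(g):
        gz = g if omega is None else (g * (omega * np.cos(omega * z))).astype(z.dtype)
        return (gz @ W.data.T, x.data.T @ gz, gz.sum(axis=0, keepdims=True))

    return Tensor._from_op(out, (x, W, b), vjp)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def vjp(g):
        return tuple(np.split(g, offsets, axis=axis))

    return Tensor._from_op(out, tuple(tensors), vjp)


def custom(
    forward: Callable[..., np.ndarray],
    vjp: Callable[..., Sequence[np.ndarray | None]],
    *inputs: Tensor,
    aux: tuple = (),
) -> Tensor:
    """Build a tape node from a kernel with a hand-written VJP.

    ``forward(*arrays, *aux)`` produces the output array;
    ``vjp(grad, out, *arrays, *aux)`` returns one cotangent per input
    (``None`` for inputs that do not need gradients).
    """
    arrays = [t.data for t in inputs]
    out_data = forward(*arrays, *aux)

    def _vjp(g):
        return vjp(g, out_data, *arrays, *aux)

    return Tensor._from_op(out_data, inputs, _vjp)
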