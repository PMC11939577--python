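"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The segmentation network in :mod:`lusseg.model` is small enough (ViT-Small/16
encoder plus a four-stage convolutional decoder) that a compact tape-based
engine over ``float32`` NumPy arrays trains it on a single CPU.  The engine
supports exactly the operations that network and its losses need: broadcasted
arithmetic, matmul, reshape/transpose/slicing, softmax, layer norm, GELU/ReLU/
sigmoid, log/exp/sqrt/clip, reductions, concatenation, 3x3 and 1x1
convolutions via im2col, batch norm, and nearest-neighbour 2x upsampling.

Gradients are accumulated by a topological sweep over the recorded graph;
every op's backward is checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference / metrics)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ---- graph plumbing -------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        else:
            out._parents = ()
            out._backward = None
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (12 transformer blocks)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph to bound memory during training
                if node is not self:
                    node.grad = None
                    node._backward = None
                    node._parents = ()

    # ---- basic arithmetic ----------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._result(data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._result(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        data = a.data / b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data),
                                           b.data.shape))

        return Tensor._result(data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        data = a.data ** p

        def backward(g):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._result(data, (a,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        data = a.data @ b.data

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._result(data, (a, b), backward)

    # ---- shape ops ------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape
        data = a.data.reshape(shape)

        def backward(g):
            a._accumulate(g.reshape(orig))

        return Tensor._result(data, (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        data = np.ascontiguousarray(a.data.transpose(axes))

        def backward(g):
            a._accumulate(g.transpose(tuple(inv)))

        return Tensor._result(data, (a,), backward)

    def __getitem__(self, idx):
        a = self
        data = a.data[idx]

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._result(np.ascontiguousarray(data), (a,), backward)

    def broadcast_to(self, shape):
        a = self
        data = np.broadcast_to(a.data, shape)

        def backward(g):
            a._accumulate(_unbroadcast(g, a.data.shape))

        return Tensor._result(np.ascontiguousarray(data), (a,), backward)

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, a.data.shape)
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                grad = np.broadcast_to(g2, a.data.shape)
            a._accumulate(np.ascontiguousarray(grad))

        return Tensor._result(np.asarray(data, dtype=np.float32), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[ax] for ax in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- elementwise nonlinearities --------------------------------------

    def relu(self):
        a = self
        data = np.maximum(a.data, 0.0)

        def backward(g):
            a._accumulate(g * (a.data > 0))

        return Tensor._result(data, (a,), backward)

    def gelu(self):
        """Gaussian error linear unit (tanh approximation, as in ViT)."""
        a = self
        c = math.sqrt(2.0 / math.pi)
        x = a.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
            a._accumulate(g * grad)

        return Tensor._result(data.astype(np.float32), (a,), backward)

    def sigmoid(self):
        a = self
        data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accumulate(g * data * (1.0 - data))

        return Tensor._result(data, (a,), backward)

    def log(self):
        a = self
        data = np.log(a.data)

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._result(data, (a,), backward)

    def exp(self):
        a = self
        data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * data)

        return Tensor._result(data, (a,), backward)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through inside [lo, hi] only."""
        a = self
        data = np.clip(a.data, lo, hi)

        def backward(g):
            a._accumulate(g * ((a.data >= lo) & (a.data <= hi)))

        return Tensor._result(data, (a,), backward)

    def softmax(self, axis: int = -1):
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * data).sum(axis=axis, keepdims=True)
            a._accumulate(data * (g - dot))

        return Tensor._result(data, (a,), backward)

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-6):
        """Normalize over the last axis, then scale and shift."""
        a = self
        x = a.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        data = xhat * weight.data + bias.data
        n = x.shape[-1]

        def backward(g):
            if weight.requires_grad:
                axes = tuple(range(g.ndim - 1))
                weight._accumulate((g * xhat).sum(axis=axes))
            if bias.requires_grad:
                axes = tuple(range(g.ndim - 1))
                bias._accumulate(g.sum(axis=axes))
            if a.requires_grad:
                gx = g * weight.data
                t1 = gx.mean(axis=-1, keepdims=True)
                t2 = (gx * xhat).mean(axis=-1, keepdims=True)
                a._accumulate(inv * (gx - t1 - xhat * t2))
            _ = n  # keep closure explicit

        return Tensor._result(data.astype(np.float32), (a, weight, bias), backward)

    # ---- spatial ops -----------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None",
               padding: int = 0) -> "Tensor":
        """NCHW convolution, stride 1, square kernel.

        Computed as k*k shifted GEMMs (one per kernel tap), which keeps every
        matmul dense and avoids the large im2col gather.
        """
        a = self
        B, C, H, W = a.data.shape
        Cout, Cin, k, k2 = weight.data.shape
        assert k == k2 and Cin == C
        if padding:
            xp = np.pad(a.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
        else:
            xp = a.data
        Ho, Wo = xp.shape[2] - k + 1, xp.shape[3] - k + 1
        L = Ho * Wo
        wf = weight.data
        acc = np.zeros((B, Cout, L), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i:i + Ho, j:j + Wo].reshape(B, C, L)
                acc += wf[:, :, i, j] @ xs
        if bias is not None:
            acc += bias.data[None, :, None]
        data = acc.reshape(B, Cout, Ho, Wo)

        parents = (a, weight) if bias is None else (a, weight, bias)

        def backward(g):
            gout = g.reshape(B, Cout, L)
            if bias is not None and bias.requires_grad:
                bias._accumulate(gout.sum(axis=(0, 2)))
            gw = np.empty_like(wf) if weight.requires_grad else None
            gxp = np.zeros_like(xp) if a.requires_grad else None
            for i in range(k):
                for j in range(k):
                    if gw is not None:
                        xs = xp[:, :, i:i + Ho, j:j + Wo].reshape(B, C, L)
                        gw[:, :, i, j] = np.tensordot(
                            gout, xs, axes=([0, 2], [0, 2]))
                    if gxp is not None:
                        gxp[:, :, i:i + Ho, j:j + Wo] += (
                            wf[:, :, i, j].T @ gout).reshape(B, C, Ho, Wo)
            if gw is not None:
                weight._accumulate(gw)
            if gxp is not None:
                if padding:
                    gxp = gxp[:, :, padding:padding + H, padding:padding + W]
                a._accumulate(np.ascontiguousarray(gxp))

        return Tensor._result(data, parents, backward)

    def upsample2x(self) -> "Tensor":
        """Nearest-neighbour 2x spatial upsampling on NCHW."""
        a = self
        data = a.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            B, C, H2, W2 = g.shape
            a._accumulate(g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

        return Tensor._result(data, (a,), backward)

    def batch_norm(self, weight: "Tensor", bias: "Tensor",
                   running_mean: np.ndarray, running_var: np.ndarray,
                   training: bool, momentum: float = 0.1,
                   eps: float = 1e-5) -> "Tensor":
        """Batch norm over (B, H, W) per channel, NCHW layout.

        ``running_mean``/``running_var`` are plain arrays updated in place
        during training and used verbatim at eval time.
        """
        a = self
        x = a.data
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            running_mean *= (1 - momentum)
            running_mean += momentum * mu
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            running_var *= (1 - momentum)
            running_var += momentum * unbiased
        else:
            mu, var = running_mean, running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        data = xhat * weight.data[None, :, None, None] + bias.data[None, :, None, None]

        def backward(g):
            axes = (0, 2, 3)
            if weight.requires_grad:
                weight._accumulate((g * xhat).sum(axis=axes))
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=axes))
            if a.requires_grad:
                gx = g * weight.data[None, :, None, None]
                if training:
                    n = x.shape[0] * x.shape[2] * x.shape[3]
                    t1 = gx.sum(axis=axes) / n
                    t2 = (gx * xhat).sum(axis=axes) / n
                    grad = inv[None, :, None, None] * (
                        gx - t1[None, :, None, None]
                        - xhat * t2[None, :, None, None])
                else:
                    grad = gx * inv[None, :, None, None]
                a._accumulate(grad.astype(np.float32))

        return Tensor._result(data.astype(np.float32), (a, weight, bias), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(np.ascontiguousarray(g[tuple(idx)]))

    return Tensor._result(data, tuple(tensors), backward)
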