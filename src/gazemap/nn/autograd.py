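"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for convolutional encoder-decoder
networks: broadcasting elementwise arithmetic, reductions, matmul, 2-D
convolution / transposed convolution / max-pooling / nearest upsampling,
sigmoid/ReLU, concatenation, and a fused softmax cross-entropy.  Arrays are
float32 in NCHW layout.

Convolutions use im2col (``sliding_window_view`` + einsum); their backward
passes scatter-add the window gradients back, so gradients are exact (checked
against finite differences in the test-suite).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "softmax_cross_entropy", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def pow(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    __pow__ = pow

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self.pow(0.5)

    # -- activations ---------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, g))
            else:
                gg = np.asarray(g)
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def matmul(self, other):
        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- spatial ops (NCHW) --------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        x, w = self.data, weight.data
        n, c, h, wdt = x.shape
        o, c2, k, _ = w.shape
        assert c == c2, f"channel mismatch {c} vs {c2}"
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
        out = np.einsum("nchwab,ocab->nohw", win, w, optimize=True)
        if bias is not None:
            out = out + bias.data.reshape(1, -1, 1, 1)
        ho, wo = out.shape[2:]

        def backward(g):
            if weight.requires_grad:
                weight._accum(np.einsum("nchwab,nohw->ocab", win, g, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dwin = np.einsum("nohw,ocab->nchwab", g, w, optimize=True)
                dxp = np.zeros_like(xp)
                for a in range(k):
                    for b in range(k):
                        dxp[:, :, a : a + ho * stride : stride,
                            b : b + wo * stride : stride] += dwin[..., a, b]
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                self._accum(dxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, backward)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None, stride: int = 2):
        """Transposed convolution with kernel == stride (non-overlapping blocks)."""
        x, w = self.data, weight.data  # w: (C_in, C_out, k, k)
        n, c, h, wdt = x.shape
        c2, o, k, _ = w.shape
        assert c == c2 and k == stride
        blocks = np.einsum("ncij,coab->noiajb", x, w, optimize=True)
        out = blocks.reshape(n, o, h * k, wdt * k)
        if bias is not None:
            out = out + bias.data.reshape(1, -1, 1, 1)

        def backward(g):
            gb = g.reshape(n, o, h, k, wdt, k)
            if weight.requires_grad:
                weight._accum(np.einsum("ncij,noiajb->coab", x, gb, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                self._accum(np.einsum("noiajb,coab->ncij", gb, w, optimize=True))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, backward)

    def maxpool2d(self, k: int = 2):
        x = self.data
        n, c, h, w = x.shape
        assert h % k == 0 and w % k == 0, "spatial dims must be divisible by pool size"
        xr = x.reshape(n, c, h // k, k, w // k, k)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first maximal position
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
        first = flat.argmax(axis=-1)
        sel = np.zeros_like(flat)
        np.put_along_axis(sel, first[..., None], 1, axis=-1)
        sel = sel.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)

        def backward(g):
            if self.requires_grad:
                gg = sel * g[:, :, :, None, :, None]
                self._accum(gg.reshape(n, c, h, w))

        return Tensor._make(out, (self,), backward)

    def upsample_nearest2d(self, scale: int = 2):
        def backward(g):
            if self.requires_grad:
                n, c, h, w = self.data.shape
                gg = g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
                self._accum(gg)

        out = np.repeat(np.repeat(self.data, scale, axis=2), scale, axis=3)
        return Tensor._make(out, (self,), backward)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow Python recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None  # free the tape as we go


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer labels (N,)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()

    def backward(g):
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(n), labels] -= 1.0
            logits._accum(g * d / n)

    return Tensor._make(np.float32(loss), (logits,), backward)
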