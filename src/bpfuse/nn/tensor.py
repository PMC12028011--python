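"""Reverse-mode autodiff on numpy arrays.

A :class:`Tensor` wraps an ndarray and records a backward closure; calling
``backward()`` on a scalar loss topologically sorts the graph and
accumulates gradients. Broadcasting in elementwise ops is handled by
summing gradients over the broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "max_reduce", "bce_with_logits", "conv3d", "maxpool3d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype != np.float32 else np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._prev: tuple[Tensor, ...] = ()
        self.name = name

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- elementwise ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            if self.requires_grad:
                self._accumulate(-out.grad)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * p * self.data ** (p - 1))

        out = self._make(out_data, (self,), backward)
        return out

    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * mask)

        out = self._make(self.data * mask, (self,), backward)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1.0 - s))

        out = self._make(s, (self,), backward)
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.ndim for a in axes)
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a % self.ndim] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(orig))

        out = self._make(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(inv))

        out = self._make(self.data.transpose(axes), (self,), backward)
        return out

    def __getitem__(self, idx):
        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

        out = self._make(self.data[idx], (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward():
            g = out.grad
            if self.requires_grad:
                if other.ndim == 1:
                    self._accumulate(_unbroadcast(np.outer(g, other.data).reshape(self.shape), self.shape))
                else:
                    self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                if self.ndim == 1:
                    other._accumulate(_unbroadcast(np.outer(self.data, g).reshape(other.shape), other.shape))
                else:
                    other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# Free functions
# ---------------------------------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out_data.ndim
                idx[axis] = slice(a, b)
                t._accumulate(out.grad[tuple(idx)])

    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def max_reduce(x: Tensor, axis) -> Tensor:
    """Max over `axis` (tuple allowed); gradient flows to (one) argmax."""
    axes = axis if isinstance(axis, tuple) else (axis,)
    axes = tuple(a % x.ndim for a in axes)
    out_data = x.data.max(axis=axes)
    expanded = np.expand_dims(out_data, axes)
    # route gradient to the first maximal element only (ties broken arbitrarily)
    mask = x.data == expanded

    def backward():
        if x.requires_grad:
            g = np.expand_dims(out.grad, axes)
            counts = mask.sum(axis=axes, keepdims=True)
            x._accumulate(np.where(mask, g / counts, 0.0))

    out = x._make(out_data, (x,), backward)
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from raw logits (numerically stable)."""
    t = np.asarray(targets, dtype=np.float64).reshape(logits.shape)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    n = z.size

    def backward():
        if logits.requires_grad:
            logits._accumulate(out.grad * (sig - t) / n)

    out = logits._make(np.asarray(loss.mean()), (logits,), backward)
    return out


# ---------------------------------------------------------------------------
# Convolution / pooling primitives
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, padding: int = 1) -> Tensor:
    """3D convolution, stride 1, via shift-and-add over kernel offsets.

    x: (B, C, D, H, W); w: (O, C, kd, kh, kw); b: (O,). Output
    (B, O, D', H', W') with D' = D + 2*padding - kd + 1 etc. The
    shift-and-add formulation (one channel-contraction per kernel offset)
    avoids the cache-hostile im2col gather.
    """
    kb = w.shape[2:]
    if any(x.shape[2 + i] + 2 * padding < kb[i] for i in range(3)):
        raise ValueError(
            f"input spatial shape {x.shape[2:]} too small for kernel {kb} "
            f"with padding {padding}"
        )
    xp = np.pad(
        x.data, ((0, 0), (0, 0)) + tuple((padding, padding) for _ in range(3))
    ) if padding else x.data
    B, C = x.shape[:2]
    O = w.shape[0]
    do, ho, wo = (x.shape[2 + i] + 2 * padding - kb[i] + 1 for i in range(3))
    wd = w.data
    out_data = np.zeros((B, do, ho, wo, O), dtype=xp.dtype)
    for i in range(kb[0]):
        for j in range(kb[1]):
            for kk in range(kb[2]):
                patch = xp[:, :, i : i + do, j : j + ho, kk : kk + wo]
                # (B,C,do,ho,wo) x (O,C) contracted over C
                out_data += np.moveaxis(patch, 1, -1) @ wd[:, :, i, j, kk].T
    out_data = np.moveaxis(out_data, -1, 1)
    if b is not None:
        out_data = out_data + b.data.reshape(1, O, 1, 1, 1).astype(out_data.dtype)

    def backward():
        g = out.grad  # (B, O, do, ho, wo)
        g_last = np.ascontiguousarray(np.moveaxis(g, 1, -1))  # (B,do,ho,wo,O)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        need_x = x.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        gmat = g_last.reshape(-1, O)
        for i in range(kb[0]):
            for j in range(kb[1]):
                for kk in range(kb[2]):
                    patch = xp[:, :, i : i + do, j : j + ho, kk : kk + wo]
                    if gw is not None:
                        pm = np.moveaxis(patch, 1, -1).reshape(-1, C)
                        gw[:, :, i, j, kk] += gmat.T @ pm
                    if need_x:
                        gpatch = g_last @ wd[:, :, i, j, kk]  # (B,do,ho,wo,C)
                        gxp[:, :, i : i + do, j : j + ho, kk : kk + wo] += np.moveaxis(
                            gpatch, -1, 1
                        )
        if gw is not None:
            w._accumulate(gw)
        if need_x:
            if padding:
                x._accumulate(
                    gxp[:, :, padding:-padding, padding:-padding, padding:-padding]
                )
            else:
                x._accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    out = x._make(out_data, parents, backward)
    return out


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch normalization over axes (0, 2, 3, 4).

    Returns ``(out, batch_mean, batch_var)`` where the statistics are plain
    arrays (for running-average updates). Fusing the whole normalization
    into one graph node avoids a dozen full-size intermediates.
    """
    axes = (0, 2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    gshape = (1, -1, 1, 1, 1)
    out_data = xhat * gamma.data.reshape(gshape) + beta.data.reshape(gshape)
    n = x.data.size // x.shape[1]

    def backward():
        g = out.grad
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data.reshape(gshape)
            mean_gs = gs.mean(axis=axes, keepdims=True)
            mean_gs_xhat = (gs * xhat).mean(axis=axes, keepdims=True)
            x._accumulate(inv_std * (gs - mean_gs - xhat * mean_gs_xhat))

    out = x._make(out_data, (x, gamma, beta), backward)
    return out, mu.ravel(), var.ravel()


def maxpool3d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping max pooling with kernel = stride = k.

    Floor mode: trailing voxels on axes not divisible by k are dropped.
    """
    B, C, D, H, W = x.shape
    if min(D, H, W) < k:
        raise ValueError(f"spatial shape {(D, H, W)} smaller than pool kernel {k}")
    Dp, Hp, Wp = (D // k) * k, (H // k) * k, (W // k) * k
    xd = x.data[:, :, :Dp, :Hp, :Wp]
    xr = xd.reshape(B, C, Dp // k, k, Hp // k, k, Wp // k, k)
    out_data = xr.max(axis=(3, 5, 7))
    expanded = out_data[:, :, :, None, :, None, :, None]
    mask = xr == expanded

    def backward():
        if x.requires_grad:
            counts = mask.sum(axis=(3, 5, 7), keepdims=True)
            g = out.grad[:, :, :, None, :, None, :, None] / counts
            gx = np.zeros_like(x.data, dtype=np.float64)
            gx[:, :, :Dp, :Hp, :Wp] = (mask * g).reshape(B, C, Dp, Hp, Wp)
            x._accumulate(gx)

    out = x._make(out_data, (x,), backward)
    return out
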