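"""Minimal reverse-mode automatic differentiation over numpy arrays.

All tensors are channels-last: ``(batch, *spatial, channels)`` with spatial
rank 2 (images) or 3 (volumes).  The op set is exactly what an encoder-decoder
segmentation network needs: size-preserving convolution (kernel 1 or 3 per
axis), 2x stride-2 transposed convolution, 2x max-pooling, batch
normalization, ReLU/sigmoid, channel concatenation, residual addition and a
pixelwise binary cross-entropy reduction.

Convolutions are evaluated as a sum of BLAS matmuls over kernel offsets
rather than one large im2col buffer; this keeps memory flat and is fast for
the 3x3/3x3x3 kernels used here.
"""

from __future__ import annotations

import itertools
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "concat",
    "relu",
    "sigmoid",
    "conv",
    "conv_transpose2x",
    "maxpool2x",
    "batch_norm",
    "bce_loss",
]


class Tensor:
    """A numpy array plus the tape entry needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backprop from a scalar tensor through the recorded tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def _needs_grad(*ts: Tensor) -> bool:
    return _GRAD_ENABLED[0] and any(t.requires_grad for t in ts)


def _result(data, parents, backward):
    req = _needs_grad(*parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents) if req else (),
                  backward=backward if req else None)


# ---------------------------------------------------------------------------
# elementwise / structural ops


def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise addition; ``b`` may broadcast (e.g. a per-channel bias)."""
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return _result(out_data, (a, b), backward)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(p)

    return _result(out_data, tuple(tensors), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g: np.ndarray) -> None:
        x.accumulate(g * mask)

    return _result(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable two-sided form
    d = x.data
    z = np.exp(-np.abs(d))
    out_data = np.where(d >= 0, 1.0 / (1.0 + z), z / (1.0 + z)).astype(d.dtype)

    def backward(g: np.ndarray) -> None:
        x.accumulate(g * out_data * (1.0 - out_data))

    return _result(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution family


def conv(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Size-preserving convolution.

    ``x``: (B, *S, C_in); ``w``: (*k, C_in, C_out) with every kernel extent
    odd (1 or 3 here); ``b``: (C_out,) or None.  Output: (B, *S, C_out).
    """
    kernel = w.data.shape[:-2]
    rank = len(kernel)
    if x.data.ndim != rank + 2:
        raise ValueError(f"input rank {x.data.ndim - 2} does not match kernel rank {rank}")
    spatial = x.data.shape[1:-1]
    pads = [(k // 2, k // 2) for k in kernel]
    if any(p != (0, 0) for p in pads):
        xp = np.pad(x.data, [(0, 0)] + pads + [(0, 0)])
    else:
        xp = x.data
    c_in = x.data.shape[-1]
    c_out = w.data.shape[-1]
    ksize = int(np.prod(kernel))
    out_shape = x.data.shape[:-1] + (c_out,)
    wr = w.data.reshape(ksize * c_in, c_out)

    def _im2col(arr: np.ndarray, channels: int) -> np.ndarray:
        if ksize == 1:
            return arr.reshape(-1, channels)
        win = np.lib.stride_tricks.sliding_window_view(
            arr, kernel, axis=tuple(range(1, 1 + rank)))  # (B, *S, C, *k)
        order = ([0] + list(range(1, 1 + rank))
                 + list(range(2 + rank, 2 + 2 * rank)) + [1 + rank])
        return np.ascontiguousarray(win.transpose(order)).reshape(-1, ksize * channels)

    col = _im2col(xp, c_in)
    out_data = (col @ wr).reshape(out_shape)
    if b is not None:
        out_data = out_data + b.data
    if not _needs_grad(x, w):
        col = None  # free the im2col buffer in inference mode

    def backward(g: np.ndarray) -> None:
        g2 = g.reshape(-1, c_out)
        if b is not None and b.requires_grad:
            b.accumulate(g2.sum(axis=0))
        if w.requires_grad:
            w.accumulate((col.T @ g2).reshape(w.data.shape))
        if x.requires_grad:
            # dL/dx is the correlation of g with the spatially flipped,
            # channel-transposed kernel — one more im2col GEMM.
            wf = w.data
            for ax in range(rank):
                wf = np.flip(wf, axis=ax)
            wf = np.ascontiguousarray(np.swapaxes(wf, -1, -2)).reshape(
                ksize * c_out, c_in)
            if any(p != (0, 0) for p in pads):
                gp = np.pad(g, [(0, 0)] + pads + [(0, 0)])
            else:
                gp = g
            gcol = _im2col(gp, c_out)
            x.accumulate((gcol @ wf).reshape(x.data.shape))

    parents = (x, w) if b is None else (x, w, b)
    return _result(out_data, parents, backward)


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with 2-per-axis kernel and stride 2.

    ``w``: (C_in, 2**rank * C_out).  Doubles every spatial extent; with
    kernel == stride the output blocks do not overlap, so the op is one
    matmul plus an interleaving reshape.
    """
    rank = x.data.ndim - 2
    batch = x.data.shape[0]
    spatial = x.data.shape[1:-1]
    c_in = x.data.shape[-1]
    c_out = w.data.shape[1] // (2 ** rank)
    blocks = (x.data.reshape(-1, c_in) @ w.data)  # (B*prod(S), 2^r * C_out)
    blocks = blocks.reshape(batch, *spatial, *([2] * rank), c_out)
    # interleave (B, S1, 2, S2, 2[, S3, 2], C)
    perm = [0]
    for i in range(rank):
        perm += [1 + i, 1 + rank + i]
    perm.append(1 + 2 * rank)
    out_data = blocks.transpose(perm).reshape(batch, *(2 * s for s in spatial), c_out)
    if b is not None:
        out_data = out_data + b.data

    def backward(g: np.ndarray) -> None:
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
        shp = [batch]
        for s in spatial:
            shp += [s, 2]
        shp.append(c_out)
        gb = g.reshape(shp)
        inv = [0] + [1 + 2 * i for i in range(rank)] + [2 + 2 * i for i in range(rank)]
        inv.append(1 + 2 * rank)
        gb = np.ascontiguousarray(gb.transpose(inv)).reshape(-1, (2 ** rank) * c_out)
        if w.requires_grad:
            w.accumulate(x.data.reshape(-1, c_in).T @ gb)
        if x.requires_grad:
            x.accumulate((gb @ w.data.T).reshape(x.data.shape))

    parents = (x, w) if b is None else (x, w, b)
    return _result(out_data, parents, backward)


def maxpool2x(x: Tensor) -> Tensor:
    """Max-pooling with window 2 and stride 2 on every spatial axis."""
    rank = x.data.ndim - 2
    batch = x.data.shape[0]
    spatial = x.data.shape[1:-1]
    channels = x.data.shape[-1]
    if any(s % 2 for s in spatial):
        raise ValueError(f"odd spatial extent in {x.data.shape}; cannot pool by 2")
    half = [s // 2 for s in spatial]
    shp = [batch]
    for h in half:
        shp += [h, 2]
    shp.append(channels)
    windows = x.data.reshape(shp)
    perm = [0] + [1 + 2 * i for i in range(rank)] + [2 + 2 * i for i in range(rank)] + [1 + 2 * rank]
    windows = windows.transpose(perm).reshape(batch, *half, 2 ** rank, channels)
    idx = windows.argmax(axis=-2)
    out_data = np.take_along_axis(windows, idx[..., None, :], axis=-2).squeeze(-2)

    def backward(g: np.ndarray) -> None:
        gw = np.zeros((batch, *half, 2 ** rank, channels), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None, :], g[..., None, :], axis=-2)
        gw = gw.reshape(batch, *half, *([2] * rank), channels)
        inv = [0]
        for i in range(rank):
            inv += [1 + i, 1 + rank + i]
        inv.append(1 + 2 * rank)
        x.accumulate(gw.transpose(inv).reshape(x.data.shape))

    return _result(out_data, (x,), backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over batch and spatial axes.

    Running statistics are updated in place when ``training`` is true
    (``running = momentum * running + (1 - momentum) * batch``).
    """
    axes = tuple(range(x.data.ndim - 1))
    c = x.data.shape[-1]
    n = x.data.size // c
    if training:
        flat = x.data.reshape(-1, c)
        mean = flat.sum(axis=0) / n
        var = np.einsum("nc,nc->c", flat, flat) / n - mean * mean
        np.maximum(var, 0.0, out=var)
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mean
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out_data = (xhat * gamma.data + beta.data).astype(x.data.dtype)

    def backward(g: np.ndarray) -> None:
        gf = g.reshape(-1, c)
        xf = xhat.reshape(-1, c)
        gsum = gf.sum(axis=0)
        gxsum = np.einsum("nc,nc->c", gf, xf)
        if beta.requires_grad:
            beta.accumulate(gsum)
        if gamma.requires_grad:
            gamma.accumulate(gxsum)
        if x.requires_grad:
            if training:
                x.accumulate(
                    (g - gsum / n - xhat * (gxsum / n)) * (gamma.data * inv_std))
            else:
                x.accumulate(g * gamma.data * inv_std)

    return _result(out_data, (x, gamma, beta), backward)


def bce_loss(pred: Tensor, target: np.ndarray, reduction: str = "mean",
             eps: float = 1e-7) -> Tensor:
    """Pixelwise binary cross-entropy of probabilities against a binary mask.

    ``reduction="sum"`` is the literal pixel sum; ``"mean"`` divides by the
    number of pixels.  Predictions are clamped to [eps, 1-eps].
    """
    if pred.data.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.data.shape} vs {target.shape}")
    p = np.clip(pred.data, eps, 1.0 - eps)
    t = np.asarray(target, dtype=p.dtype)
    elems = -(t * np.log(p) + (1.0 - t) * np.log1p(-p))
    total = elems.sum()
    scale = 1.0 if reduction == "sum" else 1.0 / pred.data.size
    out_data = np.asarray(total * scale, dtype=p.dtype)

    def backward(g: np.ndarray) -> None:
        inside = (pred.data > eps) & (pred.data < 1.0 - eps)
        dp = (p - t) / (p * (1.0 - p))
        pred.accumulate((g * scale) * np.where(inside, dp, 0.0))

    return _result(out_data, (pred,), backward)
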