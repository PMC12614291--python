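"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is a deliberately small tape-based engine providing exactly the
operations the conditional U-Net needs: broadcast add/mul, (batched)
matmul, 3x3 and 1x1 convolution, group normalisation, SiLU, 2x average
pooling, nearest-neighbour upsampling, channel concatenation, softmax and
mean-squared-error reduction.  Gradients flow only through :class:`Tensor`
leaves created with ``requires_grad=True`` (the network parameters); all
array data is float32.

Every op is validated against central finite differences in the test
suite, which is the correctness contract for everything trained with it.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "backward",
    "add",
    "mul",
    "matmul",
    "silu",
    "conv3x3",
    "conv1x1",
    "group_norm",
    "avg_pool2",
    "upsample2",
    "concat_channels",
    "softmax",
    "add_channel_bias",
    "mse_loss",
    "reshape",
    "swap_last2",
]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g


def backward(loss: Tensor) -> None:
    """Backpropagate from a scalar loss through the tape."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:  # iterative DFS; graphs can be deeper than the recursion limit
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))

    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node.backward_fn is not None:
            node.backward_fn(node.grad)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    out.backward_fn = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out.backward_fn = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports batched operands via ``np.matmul`` semantics
    for operands whose batch dimensions already match."""
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a.accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b.accumulate(_unbroadcast(gb, b.data.shape))

    out.backward_fn = bw
    return out


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(x.data * s, (x,))

    def bw(g):
        if x.requires_grad:
            x.accumulate(g * (s * (1.0 + x.data * (1.0 - s))))

    out.backward_fn = bw
    return out


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N, C*9, H*W) patches for a 3x3 kernel, zero padding 1.

    Built with nine strided slice-copies (one per kernel offset), which is
    far cheaper than a transposed gather at these sizes.
    """
    n, c, h, w = x.shape
    xp = np.zeros((n, c, h + 2, w + 2), dtype=x.dtype)
    xp[:, :, 1 : 1 + h, 1 : 1 + w] = x
    cols = np.empty((n, 9, c, h, w), dtype=x.dtype)
    for k in range(9):
        di, dj = divmod(k, 3)
        cols[:, k] = xp[:, :, di : di + h, dj : dj + w]
    return cols.reshape(n, 9 * c, h * w)


def _col2im3(gcols: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of :func:`_im2col3`."""
    n, c, h, w = shape
    g = gcols.reshape(n, 9, c, h, w)
    gxp = np.zeros((n, c, h + 2, w + 2), dtype=gcols.dtype)
    for k in range(9):
        di, dj = divmod(k, 3)
        gxp[:, :, di : di + h, dj : dj + w] += g[:, k]
    return gxp[:, :, 1 : 1 + h, 1 : 1 + w]


def conv3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3 same-padding convolution.  ``w``: (O, C, 3, 3), ``b``: (O,)."""
    n, c, h, wd = x.data.shape
    o = w.data.shape[0]
    cols = _im2col3(x.data)  # (N, 9*C, HW), offset-major
    wmat = w.data.transpose(0, 2, 3, 1).reshape(o, 9 * c)
    y = (wmat @ cols).reshape(n, o, h, wd) + b.data[None, :, None, None]
    out = Tensor(y, (x, w, b))

    def bw(g):
        gy = g.reshape(n, o, h * wd)
        if w.requires_grad:
            # single GEMM over the flattened (batch, pixel) axis
            gyf = np.ascontiguousarray(gy.transpose(1, 0, 2)).reshape(o, -1)
            colsf = np.ascontiguousarray(cols.transpose(1, 0, 2)).reshape(9 * c, -1)
            gw = (gyf @ colsf.T).reshape(o, 3, 3, c)
            w.accumulate(gw.transpose(0, 3, 1, 2))
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = wmat.T @ gy  # (N, C*9, HW)
            x.accumulate(_col2im3(gcols, x.data.shape))

    out.backward_fn = bw
    return out


def conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Pointwise convolution.  ``w``: (O, C), ``b``: (O,)."""
    n, c, h, wd = x.data.shape
    o = w.data.shape[0]
    xm = x.data.reshape(n, c, h * wd)
    y = (w.data @ xm).reshape(n, o, h, wd) + b.data[None, :, None, None]
    out = Tensor(y, (x, w, b))

    def bw(g):
        gy = g.reshape(n, o, h * wd)
        if w.requires_grad:
            gyf = np.ascontiguousarray(gy.transpose(1, 0, 2)).reshape(o, -1)
            xmf = np.ascontiguousarray(xm.transpose(1, 0, 2)).reshape(c, -1)
            w.accumulate(gyf @ xmf.T)
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x.accumulate((w.data.T @ gy).reshape(x.data.shape))

    out.backward_fn = bw
    return out


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalisation over (channels/groups, H, W) with affine params."""
    n, c, h, w = x.data.shape
    g_ = groups
    assert c % g_ == 0, "channels must divide into groups"
    xg = x.data.reshape(n, g_, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = np.maximum(
        np.einsum("ngk,ngk->ng", xg, xg)[:, :, None] / xg.shape[2] - mu**2, 0.0
    )
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, h, w)
    y = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
    out = Tensor(y, (x, gamma, beta))

    def bw(gr):
        if gamma.requires_grad:
            gamma.accumulate((gr * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(gr.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = (gr * gamma.data[None, :, None, None]).reshape(n, g_, -1)
            xh = xhat.reshape(n, g_, -1)
            m = gxhat.mean(axis=2, keepdims=True)
            mxh = (gxhat * xh).mean(axis=2, keepdims=True)
            gx = (gxhat - m - xh * mxh) * inv
            x.accumulate(gx.reshape(n, c, h, w))

    out.backward_fn = bw
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2 (spatial dims must be even)."""
    n, c, h, w = x.data.shape
    y = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    out = Tensor(y, (x,))

    def bw(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x.accumulate(gx)

    out.backward_fn = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(y, (x,))

    def bw(g):
        if x.requires_grad:
            n, c, h, w = x.data.shape
            gx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
            x.accumulate(gx)

    out.backward_fn = bw
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(g[:, :ca])
        if b.requires_grad:
            b.accumulate(g[:, ca:])

    out.backward_fn = bw
    return out


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s, (x,))

    def bw(g):
        if x.requires_grad:
            gx = (g - (g * s).sum(axis=-1, keepdims=True)) * s
            x.accumulate(gx)

    out.backward_fn = bw
    return out


def add_channel_bias(x: Tensor, b: Tensor) -> Tensor:
    """Add a (N, C) per-sample channel bias to a (N, C, H, W) map."""
    out = Tensor(x.data + b.data[:, :, None, None], (x, b))

    def bw(g):
        if x.requires_grad:
            x.accumulate(g)
        if b.requires_grad:
            b.accumulate(g.sum(axis=(2, 3)))

    out.backward_fn = bw
    return out


def reshape(x: Tensor, shape: tuple) -> Tensor:
    out = Tensor(x.data.reshape(shape), (x,))

    def bw(g):
        if x.requires_grad:
            x.accumulate(g.reshape(x.data.shape))

    out.backward_fn = bw
    return out


def swap_last2(x: Tensor) -> Tensor:
    out = Tensor(np.ascontiguousarray(np.swapaxes(x.data, -1, -2)), (x,))

    def bw(g):
        if x.requires_grad:
            x.accumulate(np.swapaxes(g, -1, -2))

    out.backward_fn = bw
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target array."""
    diff = pred.data - np.asarray(target, dtype=np.float32)
    out = Tensor(np.float32((diff**2).mean()), (pred,))

    def bw(g):
        if pred.requires_grad:
            pred.accumulate(g * 2.0 * diff / diff.size)

    out.backward_fn = bw
    return out
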