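"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the segmentation networks need: stride-1
"same"-padded (optionally dilated) 2-D convolution, 2x2/stride-2 transposed
convolution, 2x2 max pooling, bilinear resizing, global average/max pooling,
a 1-D convolution along the channel axis, elementwise add/mul with
broadcasting, relu/sigmoid, concatenation, and a fused softmax
cross-entropy.  All tensors are float32, NCHW layout.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "mul",
    "concat",
    "relu",
    "sigmoid",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "bilinear_resize",
    "global_avg_pool",
    "global_max_pool",
    "channel_conv1d",
    "softmax",
    "softmax_cross_entropy",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data, dtype=np.float32)
        # note: ascontiguousarray would promote 0-d scalars to shape (1,)
        self.data = arr if arr.flags["C_CONTIGUOUS"] else np.ascontiguousarray(arr)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free intermediate grads/graph as we go
                node._backward = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = g.astype(np.float32, copy=False)
    if t.grad is None:
        t.grad = g.copy() if g.base is not None else g
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / structural ops


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _node(out_data, tuple(tensors), bwd)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def bwd(g):
        _accum(x, g * mask)

    return _node(out_data, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    # numerically stable logistic
    s = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-x.data)),
                 np.exp(x.data) / (1.0 + np.exp(x.data))).astype(np.float32)

    def bwd(g):
        _accum(x, g * s * (1.0 - s))

    return _node(s, (x,), bwd)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, kh: int, kw: int, dilation: int,
            pad_h: int, pad_w: int) -> np.ndarray:
    """Return (N*H*W, C*kh*kw) patches of a same-padded stride-1 window."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad_h, pad_h), (pad_w, pad_w)))
    eh = dilation * (kh - 1) + 1
    ew = dilation * (kw - 1) + 1
    v = sliding_window_view(xp, (eh, ew), axis=(2, 3))
    v = v[..., ::dilation, ::dilation]  # (N, C, H, W, kh, kw)
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    return np.ascontiguousarray(cols)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           dilation: int = 1) -> Tensor:
    """Stride-1 same-padding 2-D convolution (cross-correlation).

    ``w`` has shape (out_channels, in_channels, kh, kw); kh, kw odd.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.data.shape
    o, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {ci}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sizes for same padding")
    pad_h = dilation * (kh - 1) // 2
    pad_w = dilation * (kw - 1) // 2
    cols = _im2col(x.data, kh, kw, dilation, pad_h, pad_w)
    out = cols @ w.data.reshape(o, -1).T
    if b is not None:
        out += b.data
    out_data = out.reshape(n, h, wd, o).transpose(0, 3, 1, 2)

    def bwd(g):
        gcols = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
        if w.requires_grad:
            _accum(w, (gcols.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, gcols.sum(axis=0))
        if x.requires_grad:
            # input gradient = same conv of g with the flipped, transposed kernel
            wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, kh, kw)
            gc = _im2col(g, kh, kw, dilation, pad_h, pad_w)
            gx = (gc @ wf.reshape(c, -1).T).reshape(n, h, wd, c)
            _accum(x, gx.transpose(0, 3, 1, 2))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, bwd)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2, stride-2 transposed convolution (the U-Net up-sampling step).

    ``w`` has shape (in_channels, out_channels, 2, 2); output is 2H x 2W.
    Non-overlapping, so it reduces to an einsum.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.data.shape
    ci, o, kh, kw = w.data.shape
    if ci != c or kh != 2 or kw != 2:
        raise ValueError("conv_transpose2x2 expects kernel (C_in, C_out, 2, 2)")
    out = np.einsum("nchw,coij->nohiwj", x.data, w.data, optimize=True)
    out_data = out.reshape(n, o, 2 * h, 2 * wd)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def bwd(g):
        g6 = g.reshape(n, o, h, 2, wd, 2)
        if x.requires_grad:
            _accum(x, np.einsum("nohiwj,coij->nchw", g6, w.data, optimize=True))
        if w.requires_grad:
            _accum(w, np.einsum("nchw,nohiwj->coij", x.data, g6, optimize=True))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    ho, wo = h // 2, w // 2
    r = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, ho, wo, 4)
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gr = np.zeros((n, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accum(x, gx.reshape(n, c, h, w))

    return _node(out_data, (x,), bwd)


@lru_cache(maxsize=64)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (n_out x n_in), rows sum to 1."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        a[o, i0c] += 1.0 - frac
        a[o, i1c] += frac
    return a


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize (half-pixel-centre convention)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    ah = _interp_matrix(h, out_h)
    aw = _interp_matrix(w, out_w)
    x2 = x.data.reshape(n * c, h, w)
    out = np.matmul(np.matmul(ah, x2), aw.T)
    out_data = out.reshape(n, c, out_h, out_w)

    def bwd(g):
        g2 = g.reshape(n * c, out_h, out_w)
        gx = np.matmul(np.matmul(ah.T, g2), aw)
        _accum(x, gx.reshape(n, c, h, w))

    return _node(out_data, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def bwd(g):
        _accum(x, np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return _node(out_data, (x,), bwd)


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial maximum."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gx = np.zeros((n, c, h * w), dtype=np.float32)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
        _accum(x, gx.reshape(n, c, h, w))

    return _node(out_data, (x,), bwd)


def channel_conv1d(v: Tensor, w: Tensor) -> Tensor:
    """1-D convolution along the channel axis of a (N, C) descriptor.

    ``w`` is a length-K (K odd) kernel shared across channels and batch;
    zero padding keeps C unchanged.
    """
    v, w = _as_tensor(v), _as_tensor(w)
    n, c = v.data.shape
    k = w.data.shape[0]
    if k % 2 == 0:
        raise ValueError("channel kernel length K must be odd")
    p = k // 2
    vp = np.pad(v.data, ((0, 0), (p, p)))
    windows = sliding_window_view(vp, k, axis=1)  # (N, C, K)
    out_data = windows @ w.data

    def bwd(g):
        if w.requires_grad:
            _accum(w, np.einsum("nck,nc->k", windows, g, optimize=True))
        if v.requires_grad:
            gp = np.pad(g, ((0, 0), (p, p)))
            gwin = sliding_window_view(gp, k, axis=1)
            _accum(v, gwin @ w.data[::-1].copy())

    return _node(out_data, (v, w), bwd)


# ---------------------------------------------------------------------------
# softmax / loss


def softmax_np(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Softmax (forward-only convenience; training uses the fused loss)."""
    x = _as_tensor(x)
    s = softmax_np(x.data, axis=axis)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        _accum(x, s * (g - dot))

    return _node(s.astype(np.float32), (x,), bwd)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          class_weights: np.ndarray | None = None) -> Tensor:
    """Mean per-pixel weighted cross-entropy of softmax(logits) vs labels.

    logits: (N, C, H, W); labels: (N, H, W) integer class ids;
    class_weights: (C,) per-class loss weights (broadcast over pixels).
    Normalized by the total number of pixels in the batch.
    """
    logits = _as_tensor(logits)
    n, c, h, w = logits.data.shape
    labels = np.asarray(labels)
    if labels.shape != (n, h, w):
        raise ValueError(f"labels shape {labels.shape} != {(n, h, w)}")
    p = softmax_np(logits.data.astype(np.float64), axis=1)
    npix = n * h * w
    if class_weights is None:
        class_weights = np.ones(c)
    cw = np.asarray(class_weights, dtype=np.float64)
    wpix = cw[labels]  # (N, H, W)
    pt = np.take_along_axis(p, labels[:, None], axis=1)[:, 0]
    loss = float(-(wpix * np.log(np.maximum(pt, 1e-12))).sum() / npix)

    def bwd(g):
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
        gx = (p - onehot) * wpix[:, None] * (float(np.sum(g)) / npix)
        _accum(logits, gx.astype(np.float32))

    return _node(np.float32(loss), (logits,), bwd)
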