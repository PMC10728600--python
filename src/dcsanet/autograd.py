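"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network is small (well under a million parameters) and is
trained on a CPU, so the whole compute graph lives comfortably in numpy.
``Var`` wraps an ndarray and records a closure that propagates the adjoint to
its parents; ``backward`` runs the closures in reverse topological order.

Convolutions are evaluated with a loop over kernel offsets: each offset
contributes a strided-view multiply (depthwise) or a ``tensordot`` over the
channel axis (dense), so the inner work is always a BLAS call and no im2col
buffer is materialised.  Bilinear resampling is expressed as two small dense
interpolation matrices applied along the spatial axes, which makes its
adjoint an exact transpose.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var",
    "add",
    "mul",
    "concat",
    "split",
    "relu",
    "sigmoid",
    "conv2d",
    "depthwise_conv2d",
    "batch_norm",
    "max_pool2x2",
    "global_avg_pool",
    "bilinear_resize",
    "take_channels",
    "scale_channels",
    "softmax_cross_entropy",
]


class Var:
    """Node in the compute graph: an array plus an adjoint accumulator."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Reverse-mode sweep seeding ``self.grad`` with ``grad`` (default 1)."""
        topo, seen = [], set()
        stack = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Var(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _as_var(x):
    return x if isinstance(x, Var) else Var(x)


# ---------------------------------------------------------------------------
# elementwise / structural ops


def add(a: Var, b: Var) -> Var:
    a, b = _as_var(a), _as_var(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return Var(out_data, parents=(a, b), backward=bwd)


def mul(a: Var, b: Var) -> Var:
    a, b = _as_var(a), _as_var(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * b.data)
        if b.requires_grad:
            b.accumulate(g * a.data)

    return Var(out_data, parents=(a, b), backward=bwd)


def concat(parts, axis=1) -> Var:
    parts = [_as_var(p) for p in parts]
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                p.accumulate(g[tuple(idx)])

    return Var(out_data, parents=tuple(parts), backward=bwd)


def split(x: Var, sections, axis=1):
    """Split into equal-size ``sections`` along ``axis``; returns list of Var."""
    x = _as_var(x)
    chunks = np.split(x.data, sections, axis=axis)
    size = chunks[0].shape[axis]
    outs = []
    for i, c in enumerate(chunks):
        def bwd(g, i=i):
            if x.requires_grad:
                full = np.zeros_like(x.data)
                idx = [slice(None)] * x.data.ndim
                idx[axis] = slice(i * size, (i + 1) * size)
                full[tuple(idx)] = g
                x.accumulate(full)
        outs.append(Var(c, parents=(x,), backward=bwd))
    return outs


def relu(x: Var) -> Var:
    x = _as_var(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return Var(out_data, parents=(x,), backward=bwd)


def sigmoid(x: Var) -> Var:
    x = _as_var(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    return Var(s, parents=(x,), backward=bwd)


def take_channels(x: Var, perm) -> Var:
    """Permute the channel axis (NCHW) by integer index array ``perm``."""
    x = _as_var(x)
    perm = np.asarray(perm)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    out_data = x.data[:, perm]

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g[:, inv])

    return Var(out_data, parents=(x,), backward=bwd)


def scale_channels(x: Var, gate: Var) -> Var:
    """Multiply an NCHW map by per-(sample,channel) gate of shape (N, C)."""
    x, gate = _as_var(x), _as_var(gate)
    g4 = gate.data[:, :, None, None]
    out_data = x.data * g4

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * g4)
        if gate.requires_grad:
            gate.accumulate((g * x.data).sum(axis=(2, 3)))

    return Var(out_data, parents=(x, gate), backward=bwd)


# ---------------------------------------------------------------------------
# convolutions


def _pad_hw(x, ph, pw):
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def conv2d(x: Var, w: Var, bias: Var | None = None, stride=(1, 1), padding=None) -> Var:
    """Dense 2-D convolution (cross-correlation), NCHW / OIHW layout.

    ``padding=None`` means "same" for stride 1 and the conventional
    ``k // 2`` halo for stride 2 (output = ceil(in / stride) for odd k).
    """
    x, w = _as_var(x), _as_var(w)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    co, ci, kh, kw = w.data.shape
    if padding is None:
        padding = (kh // 2, kw // 2)
    ph, pw = padding
    xp = _pad_hw(x.data, ph, pw)
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    out = np.zeros((n, co, ho, wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + ho * sh : sh, j : j + wo * sw : sw]
            # (n,c,ho,wo) x (co,c) -> (n,co,ho,wo)
            out += np.tensordot(patch, w.data[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
    if bias is not None:
        out += bias.data[None, :, None, None]

    parents = (x, w) if bias is None else (x, w, bias)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias.accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, :, i : i + ho * sh : sh, j : j + wo * sw : sw]
                    # sum over n,ho,wo -> (co, ci)
                    dw[:, :, i, j] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
            w.accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    # (n,co,ho,wo) x (co,ci) -> (n,ci,ho,wo)
                    contrib = np.tensordot(g, w.data[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
                    dxp[:, :, i : i + ho * sh : sh, j : j + wo * sw : sw] += contrib
            if ph or pw:
                dxp = dxp[:, :, ph : hp - ph, pw : wp - pw]
            x.accumulate(dxp)

    return Var(out, parents=parents, backward=bwd)


def depthwise_conv2d(x: Var, w: Var, stride=(1, 1), padding=None) -> Var:
    """Depthwise convolution; ``w`` has shape (C, kh, kw), one filter per channel."""
    x, w = _as_var(x), _as_var(w)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    c, kh, kw = w.data.shape
    if padding is None:
        padding = (kh // 2, kw // 2)
    ph, pw = padding
    xp = _pad_hw(x.data, ph, pw)
    n, _, hp, wp = xp.shape
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    out = np.zeros((n, c, ho, wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + ho * sh : sh, j : j + wo * sw : sw]
            out += patch * w.data[None, :, i, j, None, None]

    def bwd(g):
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, :, i : i + ho * sh : sh, j : j + wo * sw : sw]
                    dw[:, i, j] = (g * patch).sum(axis=(0, 2, 3))
            w.accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + ho * sh : sh, j : j + wo * sw : sw] += (
                        g * w.data[None, :, i, j, None, None]
                    )
            if ph or pw:
                dxp = dxp[:, :, ph : hp - ph, pw : wp - pw]
            x.accumulate(dxp)

    return Var(out, parents=(x, w), backward=bwd)


# ---------------------------------------------------------------------------
# normalisation / pooling / resampling


def batch_norm(x: Var, gamma: Var, beta: Var, running_mean, running_var,
               training: bool, momentum=0.1, eps=1e-5) -> Var:
    """Batch normalisation over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain ndarrays updated in place when
    ``training`` is true (outside the differentiated graph).
    """
    x, gamma, beta = _as_var(x), _as_var(gamma), _as_var(beta)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        # unbiased estimate for the running variance, as is conventional
        running_var *= 1 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g):
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gg = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                sum_gg = gg.sum(axis=(0, 2, 3))
                sum_gg_xhat = (gg * xhat).sum(axis=(0, 2, 3))
                dx = (inv_std[None, :, None, None] / m) * (
                    m * gg
                    - sum_gg[None, :, None, None]
                    - xhat * sum_gg_xhat[None, :, None, None]
                )
            else:
                dx = gg * inv_std[None, :, None, None]
            x.accumulate(dx)

    return Var(out, parents=(x, gamma, beta), backward=bwd)


def max_pool2x2(x: Var) -> Var:
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""
    x = _as_var(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 requires even spatial dims, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        if x.requires_grad:
            dwin = np.zeros_like(win)
            np.put_along_axis(dwin, arg[..., None], g[..., None], axis=-1)
            dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
                n, c, h, w
            )
            x.accumulate(dx)

    return Var(out, parents=(x,), backward=bwd)


def global_avg_pool(x: Var) -> Var:
    """Mean over H, W -> (N, C)."""
    x = _as_var(x)
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return Var(out, parents=(x,), backward=bwd)


def _interp_matrix(n_out, n_in, dtype):
    """Dense (n_out, n_in) bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = src - i0
    m[np.arange(n_out), i0] += 1 - f
    m[np.arange(n_out), i1] += f
    return m


def bilinear_resize(x: Var, out_hw) -> Var:
    """Bilinear resize to (H_out, W_out) with half-pixel alignment."""
    x = _as_var(x)
    n, c, h, w = x.data.shape
    ho, wo = out_hw
    mh = _interp_matrix(ho, h, x.data.dtype)
    mw = _interp_matrix(wo, w, x.data.dtype)
    # y = M_h @ x @ M_w^T along the spatial axes
    tmp = np.tensordot(x.data, mh, axes=([2], [1]))  # (n,c,w,ho)
    out = np.tensordot(tmp, mw, axes=([2], [1]))  # (n,c,ho,wo)

    def bwd(g):
        if x.requires_grad:
            t = np.tensordot(g, mw, axes=([3], [0]))  # (n,c,ho,w)
            dx = np.tensordot(t, mh, axes=([2], [0]))  # (n,c,w,h) -> fix axes
            x.accumulate(dx.transpose(0, 1, 3, 2))

    return Var(out, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# loss


def softmax_cross_entropy(logits: Var, labels: np.ndarray) -> Var:
    """Mean per-pixel cross-entropy of softmax(logits) against integer labels.

    ``logits``: (N, K, H, W); ``labels``: (N, H, W) integers in [0, K).
    The mean runs over every pixel in the batch.
    """
    logits = _as_var(logits)
    n, k, h, w = logits.data.shape
    if labels.shape != (n, h, w):
        raise ValueError(f"label shape {labels.shape} does not match logits {(n, h, w)}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    npix = n * h * w
    idx_n, idx_h, idx_w = np.meshgrid(
        np.arange(n), np.arange(h), np.arange(w), indexing="ij"
    )
    logp_true = z[idx_n, labels, idx_h, idx_w] - np.log(ez.sum(axis=1))[idx_n, idx_h, idx_w]
    loss = -logp_true.sum() / npix

    def bwd(g):
        if logits.requires_grad:
            dp = p.copy()
            np.subtract.at(dp, (idx_n, labels, idx_h, idx_w), 1.0)
            logits.accumulate(dp * (g / npix))

    return Var(np.asarray(loss), parents=(logits,), backward=bwd)
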