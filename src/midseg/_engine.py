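"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Everything the segmentation network needs — 2-D convolution, depthwise
convolution, batch normalization, bilinear resizing, pooling, elementwise
arithmetic with broadcasting, and a fused softmax cross-entropy — is
implemented as a small set of differentiable ops over an NHWC tensor
layout, plus a Module/Layer system with named parameters and an Adam
optimizer.

Convolutions use a "shift-and-GEMM" scheme: the forward pass accumulates
one matrix product per kernel tap over strided views of the padded input,
and the backward pass mirrors those shifts to scatter gradients, so no
im2col buffer is ever materialized.  Gradients of every op are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "no_grad",
    "is_grad_enabled",
    "conv2d",
    "depthwise_conv2d",
    "batch_norm",
    "max_pool2d",
    "resize_bilinear",
    "bilinear_matrix",
    "relu",
    "sigmoid",
    "concat",
    "reduce_mean",
    "reduce_sum",
    "maximum_scalar",
    "square",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]

# ---------------------------------------------------------------------------
# Tensor and tape

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self._backward = None
        self._parents = ()
        self.requires_grad = bool(requires_grad)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"

    # -- graph construction -------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse-mode sweep from this node (typically a scalar loss)."""
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
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
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience arithmetic (used sparingly; heavy lifting is in named ops)
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __truediv__(self, other):
        return div(self, _as_tensor(other))


class Parameter(Tensor):
    """A trainable (or tracked, e.g. BN statistics) weight array."""

    __slots__ = ("name", "trainable")

    def __init__(self, data, name="", trainable=True):
        super().__init__(np.asarray(data), requires_grad=trainable)
        self.name = name
        self.trainable = trainable


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward):
    """Create a graph node; drops the tape when gradients are disabled."""
    out = Tensor(data)
    if is_grad_enabled() and any(
        p.requires_grad or p._parents or p._backward for p in parents
    ):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _sum_to_shape(g, shape):
    """Reduce a broadcast gradient back to the original operand shape."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / reduction ops


def add(a, b):
    def bwd(g):
        a._accumulate(_sum_to_shape(g, a.shape))
        b._accumulate(_sum_to_shape(g, b.shape))

    return _node(a.data + b.data, (a, b), bwd)


def sub(a, b):
    def bwd(g):
        a._accumulate(_sum_to_shape(g, a.shape))
        b._accumulate(_sum_to_shape(-g, b.shape))

    return _node(a.data - b.data, (a, b), bwd)


def mul(a, b):
    def bwd(g):
        a._accumulate(_sum_to_shape(g * b.data, a.shape))
        b._accumulate(_sum_to_shape(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), bwd)


def div(a, b):
    def bwd(g):
        a._accumulate(_sum_to_shape(g / b.data, a.shape))
        b._accumulate(_sum_to_shape(-g * a.data / (b.data * b.data), b.shape))

    return _node(a.data / b.data, (a, b), bwd)


def square(a):
    def bwd(g):
        a._accumulate(2.0 * a.data * g)

    return _node(np.square(a.data), (a,), bwd)


def relu(a):
    mask = a.data > 0

    def bwd(g):
        a._accumulate(g * mask)

    return _node(np.where(mask, a.data, 0), (a,), bwd)


def sigmoid(a):
    y = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        a._accumulate(g * y * (1.0 - y))

    return _node(y, (a,), bwd)


def maximum_scalar(a, c):
    """max(a, c) for scalar c; the gradient flows only where a > c."""
    mask = a.data > c

    def bwd(g):
        a._accumulate(g * mask)

    return _node(np.where(mask, a.data, c), (a,), bwd)


def reduce_mean(a, axis, keepdims=True):
    axis = tuple(axis) if isinstance(axis, (tuple, list)) else (axis,)
    n = 1
    for ax in axis:
        n *= a.shape[ax]
    y = a.data.mean(axis=axis, keepdims=keepdims)

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g / n, a.shape))

    return _node(y, (a,), bwd)


def reduce_sum(a, axis, keepdims=True):
    axis = tuple(axis) if isinstance(axis, (tuple, list)) else (axis,)
    y = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape))

    return _node(y, (a,), bwd)


def concat(tensors, axis=-1):
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# convolution family (NHWC; weights HWIO)


def _pad_amounts(k, dilation, padding):
    """Symmetric padding for 'same' stride-1 semantics, or explicit pairs."""
    if padding == "same":
        eff = (k - 1) * dilation
        return eff // 2, eff - eff // 2
    if padding == "valid":
        return 0, 0
    return padding  # explicit (lo, hi)


def conv2d(x, w, b=None, stride=1, dilation=1, padding="same"):
    """2-D convolution, NHWC input, HWIO weights, optional bias.

    ``padding`` is 'same' (stride-1 shape-preserving), 'valid', or an
    explicit ((top, bottom), (left, right)) pair — the latter mirrors the
    explicit-pad-then-valid convention of the reference backbone.

    1x1 convolutions reduce to a single GEMM; larger kernels use one
    im2col gather (kept for the backward pass) and one GEMM.
    """
    kh, kw, cin, cout = w.shape
    if isinstance(padding, str):
        ph = _pad_amounts(kh, dilation, padding)
        pw = _pad_amounts(kw, dilation, padding)
    else:
        ph, pw = padding
    xd = x.data
    n = xd.shape[0]

    if kh == 1 and kw == 1:
        xs = xd[:, ::stride, ::stride, :] if stride > 1 else xd
        ho, wo = xs.shape[1], xs.shape[2]
        y = np.ascontiguousarray(xs).reshape(-1, cin) @ w.data[0, 0]
        if b is not None:
            y += b.data
        y = y.reshape(n, ho, wo, cout)
        parents = (x, w) if b is None else (x, w, b)

        def bwd1(g):
            gf = g.reshape(-1, cout)
            if b is not None:
                b._accumulate(g.sum(axis=(0, 1, 2)))
            w._accumulate(
                (np.ascontiguousarray(xs).reshape(-1, cin).T @ gf).reshape(w.shape)
            )
            if x.requires_grad or x._parents or x._backward:
                dxs = (gf @ w.data[0, 0].T).reshape(n, ho, wo, cin)
                if stride > 1:
                    dx = np.zeros_like(xd)
                    dx[:, ::stride, ::stride, :] = dxs
                else:
                    dx = dxs
                x._accumulate(dx)

        return _node(y, parents, bwd1)

    xp = np.pad(xd, ((0, 0), ph, pw, (0, 0))) if (ph != (0, 0) or pw != (0, 0)) else xd
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - (kh - 1) * dilation - 1) // stride + 1
    wo = (wp - (kw - 1) * dilation - 1) // stride + 1

    # im2col with channels innermost: contiguous (N*Ho*Wo, kh*kw*C)
    eff_h = (kh - 1) * dilation + 1
    eff_w = (kw - 1) * dilation + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (eff_h, eff_w), axis=(1, 2))
    win = win[:, ::stride, ::stride, :, ::dilation, ::dilation]
    # (N, Ho, Wo, C, kh, kw) -> (N, Ho, Wo, kh, kw, C): C stays unit-stride
    cols = np.ascontiguousarray(np.transpose(win, (0, 1, 2, 4, 5, 3))).reshape(
        n * ho * wo, kh * kw * cin
    )
    wmat = w.data.reshape(kh * kw * cin, cout)
    y = cols @ wmat
    if b is not None:
        y += b.data
    y = y.reshape(n, ho, wo, cout)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gf = g.reshape(-1, cout)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        w._accumulate((cols.T @ gf).reshape(w.shape))
        if x.requires_grad or x._parents or x._backward:
            dcols = (gf @ wmat.T).reshape(n, ho, wo, kh, kw, cin)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[
                        :,
                        i * dilation : i * dilation + (ho - 1) * stride + 1 : stride,
                        j * dilation : j * dilation + (wo - 1) * stride + 1 : stride,
                        :,
                    ] += dcols[:, :, :, i, j, :]
            x._accumulate(dxp[:, ph[0] : hp - ph[1], pw[0] : wp - pw[1], :])

    return _node(y, parents, bwd)


def depthwise_conv2d(x, w, stride=1, dilation=1, padding="same"):
    """Depthwise 3x3-style convolution; weights (kh, kw, C), multiplier 1."""
    kh, kw, c = w.shape
    ph = _pad_amounts(kh, dilation, padding)
    pw = _pad_amounts(kw, dilation, padding)
    xd = x.data
    n = xd.shape[0]
    xp = np.pad(xd, ((0, 0), ph, pw, (0, 0)))
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - (kh - 1) * dilation - 1) // stride + 1
    wo = (wp - (kw - 1) * dilation - 1) // stride + 1

    y = np.zeros((n, ho, wo, c), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            sl = xp[
                :,
                i * dilation : i * dilation + (ho - 1) * stride + 1 : stride,
                j * dilation : j * dilation + (wo - 1) * stride + 1 : stride,
                :,
            ]
            y += sl * w.data[i, j]

    def bwd(g):
        need_dx = x.requires_grad or x._parents or x._backward
        dxp = np.zeros_like(xp) if need_dx else None
        dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                hsl = slice(i * dilation, i * dilation + (ho - 1) * stride + 1, stride)
                wsl = slice(j * dilation, j * dilation + (wo - 1) * stride + 1, stride)
                dw[i, j] = (xp[:, hsl, wsl, :] * g).sum(axis=(0, 1, 2))
                if need_dx:
                    dxp[:, hsl, wsl, :] += g * w.data[i, j]
        w._accumulate(dw)
        if need_dx:
            x._accumulate(dxp[:, ph[0] : hp - ph[1], pw[0] : wp - pw[1], :])

    return _node(y, (x, w), bwd)


def max_pool2d(x, pool=3, stride=2, padding=((1, 1), (1, 1))):
    """Max pooling with explicit padding (padded with -inf).

    The backward pass routes each gradient to the first maximal window
    position (argmax tie rule), matching the forward tap scan order.
    """
    xd = x.data
    n, h, w, c = xd.shape
    ph, pw = padding
    xp = np.pad(xd, ((0, 0), ph, pw, (0, 0)), constant_values=-np.inf)
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - pool) // stride + 1
    wo = (wp - pool) // stride + 1

    def tap(i, j):
        return xp[:, i : i + (ho - 1) * stride + 1 : stride,
                  j : j + (wo - 1) * stride + 1 : stride, :]

    y = tap(0, 0).copy()
    for i in range(pool):
        for j in range(pool):
            if i or j:
                np.maximum(y, tap(i, j), out=y)

    def bwd(g):
        dxp = np.zeros_like(xp)
        routed = np.zeros(y.shape, dtype=bool)
        for i in range(pool):
            for j in range(pool):
                hit = (tap(i, j) == y) & ~routed
                routed |= hit
                dxp[:, i : i + (ho - 1) * stride + 1 : stride,
                    j : j + (wo - 1) * stride + 1 : stride, :] += g * hit
        x._accumulate(dxp[:, ph[0] : hp - ph[1], pw[0] : wp - pw[1], :])

    return _node(y, (x,), bwd)


def bilinear_matrix(n_out, n_in, dtype=np.float64):
    """Dense 1-D bilinear interpolation matrix, half-pixel-center convention.

    Output sample o reads source coordinate (o + 0.5) * n_in / n_out - 0.5,
    clipped to the valid range (align_corners=False semantics).
    """
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def _interp_1d(n_out, n_in, dtype):
    """(lo, hi, frac) gather indices/weights, half-pixel-center convention."""
    if n_in == 1:
        z = np.zeros(n_out, dtype=int)
        return z, z, np.zeros(n_out, dtype=dtype)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    return lo, hi, (src - lo).astype(dtype)


def resize_bilinear(x, out_h, out_w):
    """Bilinear resize along the two spatial axes of an NHWC tensor.

    Forward is a separable gather-and-lerp; backward applies the exact
    transpose of the interpolation (as small dense matrix products over
    the spatial axes).
    """
    h, w = x.shape[1], x.shape[2]
    dt = x.dtype
    hlo, hhi, hf = _interp_1d(out_h, h, dt)
    wlo, whi, wf = _interp_1d(out_w, w, dt)

    xd = x.data
    t = xd[:, hlo] * (1.0 - hf)[None, :, None, None] + xd[:, hhi] * hf[None, :, None, None]
    y = t[:, :, wlo] * (1.0 - wf)[None, None, :, None] + t[:, :, whi] * wf[None, None, :, None]

    def bwd(g):
        lh = bilinear_matrix(out_h, h, dtype=dt)
        lw = bilinear_matrix(out_w, w, dtype=dt)
        n, _, _, c = g.shape
        # contract H: (h, oh) @ (oh, n*ow*c)
        gt = np.ascontiguousarray(np.transpose(g, (1, 0, 2, 3))).reshape(out_h, -1)
        t1 = (lh.T @ gt).reshape(h, n, out_w, c)
        # contract W: (w, ow) @ (ow, n*h*c)
        t1 = np.ascontiguousarray(np.transpose(t1, (2, 1, 0, 3))).reshape(out_w, -1)
        t2 = (lw.T @ t1).reshape(w, n, h, c)
        x._accumulate(np.ascontiguousarray(np.transpose(t2, (1, 2, 0, 3))))

    return _node(np.ascontiguousarray(y), (x,), bwd)


def batch_norm(x, gamma, beta, moving_mean, moving_var, training, momentum=0.9, eps=1e-3):
    """Per-channel batch normalization over an NHWC tensor.

    In training mode the batch statistics normalize the activations and the
    moving averages are updated in place (outside the tape).  In inference
    mode the op is the affine transform given by the stored statistics.
    """
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 1, 2))
        var = xd.var(axis=(0, 1, 2))
        moving_mean.data *= momentum
        moving_mean.data += (1.0 - momentum) * mean
        moving_var.data *= momentum
        moving_var.data += (1.0 - momentum) * var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (xd - mean) * inv
        y = gamma.data * xhat + beta.data

        def bwd(g):
            m = xd.shape[0] * xd.shape[1] * xd.shape[2]
            gamma._accumulate((g * xhat).sum(axis=(0, 1, 2)))
            beta._accumulate(g.sum(axis=(0, 1, 2)))
            gxh = g * gamma.data
            t1 = gxh.sum(axis=(0, 1, 2)) / m
            t2 = (gxh * xhat).sum(axis=(0, 1, 2)) / m
            x._accumulate(inv * (gxh - t1 - xhat * t2))

        return _node(y, (x, gamma, beta), bwd)

    inv = 1.0 / np.sqrt(moving_var.data + eps)
    scale = gamma.data * inv
    shift = beta.data - moving_mean.data * scale
    y = xd * scale + shift

    def bwd(g):
        gamma._accumulate((g * (xd - moving_mean.data) * inv).sum(axis=(0, 1, 2)))
        beta._accumulate(g.sum(axis=(0, 1, 2)))
        x._accumulate(g * scale)

    return _node(y, (x, gamma, beta), bwd)


def add_relu(a, b):
    """Fused residual join: relu(a + b)."""
    y = np.maximum(a.data + b.data, 0)

    def bwd(g):
        gm = np.where(y > 0, g, 0)
        a._accumulate(gm)
        b._accumulate(gm)

    return _node(y, (a, b), bwd)


def conv_bn_act(x, w, gamma, beta, moving_mean, moving_var, training,
                b=None, stride=1, dilation=1, padding="same", momentum=0.9,
                eps=1e-3, act="relu"):
    """Fused convolution -> batch norm -> (optional) ReLU.

    Mathematically identical to ``conv2d`` (bias-free) followed by
    ``batch_norm`` and ``relu``; fusing lets the normalization run in
    place on the GEMM output, which matters on memory-bound CPUs.  The
    backward pass recovers xhat from the stored pre-activation as
    (z - beta) / gamma, so it assumes gamma stays away from exactly zero
    (guarded with a tiny floor).
    """
    kh, kw, cin, cout = w.shape
    if isinstance(padding, str):
        ph = _pad_amounts(kh, dilation, padding)
        pw = _pad_amounts(kw, dilation, padding)
    else:
        ph, pw = padding
    xd = x.data
    n = xd.shape[0]

    if kh == 1 and kw == 1:
        xs = xd[:, ::stride, ::stride, :] if stride > 1 else xd
        ho, wo = xs.shape[1], xs.shape[2]
        cols = xs.reshape(-1, cin) if xs.flags.c_contiguous else np.ascontiguousarray(xs).reshape(-1, cin)
        wmat = w.data[0, 0]
        xp = hp = wp = None
    else:
        xp = np.pad(xd, ((0, 0), ph, pw, (0, 0))) if (ph != (0, 0) or pw != (0, 0)) else xd
        hp, wp = xp.shape[1], xp.shape[2]
        ho = (hp - (kh - 1) * dilation - 1) // stride + 1
        wo = (wp - (kw - 1) * dilation - 1) // stride + 1
        eff_h = (kh - 1) * dilation + 1
        eff_w = (kw - 1) * dilation + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (eff_h, eff_w), axis=(1, 2))
        win = win[:, ::stride, ::stride, :, ::dilation, ::dilation]
        cols = np.ascontiguousarray(np.transpose(win, (0, 1, 2, 4, 5, 3))).reshape(
            n * ho * wo, kh * kw * cin
        )
        wmat = w.data.reshape(kh * kw * cin, cout)

    z = cols @ wmat  # (P, F)
    if b is not None:
        z += b.data
    p_count = z.shape[0]

    if training:
        mean = z.mean(axis=0)
        sq = np.einsum("pf,pf->f", z, z) / p_count
        var = np.maximum(sq - mean * mean, 0.0)
        moving_mean.data *= momentum
        moving_mean.data += (1.0 - momentum) * mean
        moving_var.data *= momentum
        moving_var.data += (1.0 - momentum) * var
    else:
        mean = moving_mean.data
        var = moving_var.data
    inv = 1.0 / np.sqrt(var + eps)
    scale = gamma.data * inv
    shift = beta.data - mean * scale
    z *= scale
    z += shift  # z is now the BN output (pre-activation)
    out = np.maximum(z, 0) if act == "relu" else z
    y = out.reshape(n, ho, wo, cout)

    def bwd(g):
        gf = g.reshape(-1, cout)
        if act == "relu":
            gf = np.where(z > 0, gf, 0)
        g_safe = np.where(np.abs(gamma.data) < 1e-20, 1e-20, gamma.data)
        xhat = (z - beta.data) / g_safe
        gamma._accumulate(np.einsum("pf,pf->f", gf, xhat))
        beta._accumulate(gf.sum(axis=0))
        if training:
            gxh = gf * gamma.data
            t1 = gxh.mean(axis=0)
            t2 = np.einsum("pf,pf->f", gxh, xhat) / p_count
            dz = inv * (gxh - t1 - xhat * t2)
        else:
            dz = gf * scale
        if b is not None:
            b._accumulate(dz.sum(axis=0))
        w._accumulate((cols.T @ dz).reshape(w.shape))
        if x.requires_grad or x._parents or x._backward:
            dcols = dz @ wmat.T
            if kh == 1 and kw == 1:
                dxs = dcols.reshape(n, ho, wo, cin)
                if stride > 1:
                    dx = np.zeros_like(xd)
                    dx[:, ::stride, ::stride, :] = dxs
                else:
                    dx = dxs
                x._accumulate(dx)
            else:
                dcols = dcols.reshape(n, ho, wo, kh, kw, cin)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[
                            :,
                            i * dilation : i * dilation + (ho - 1) * stride + 1 : stride,
                            j * dilation : j * dilation + (wo - 1) * stride + 1 : stride,
                            :,
                        ] += dcols[:, :, :, i, j, :]
                x._accumulate(dxp[:, ph[0] : hp - ph[1], pw[0] : wp - pw[1], :])

    return _node(y, (x, w, gamma, beta), bwd)


# ---------------------------------------------------------------------------
# losses


def softmax(logits_data):
    """Plain ndarray softmax over the last axis (inference utility)."""
    z = logits_data - logits_data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean categorical cross-entropy over all pixels.

    ``labels`` is an integer array broadcastable to logits.shape[:-1].
    Fused op: the backward pass is (softmax - onehot) / n_pixels.
    """
    p = softmax(logits.data)
    n_pix = int(np.prod(labels.shape))
    idx = np.ogrid[tuple(slice(s) for s in labels.shape)]
    picked = p[tuple(idx) + (labels,)]
    loss = -np.log(np.maximum(picked, 1e-12)).mean()

    def bwd(g):
        d = p.copy()
        d[tuple(idx) + (labels,)] -= 1.0
        logits._accumulate(g * d / n_pix)

    return _node(np.asarray(loss, dtype=logits.dtype), (logits,), bwd)


# ---------------------------------------------------------------------------
# Module system


class Module:
    """Base class with automatic sub-layer registration and parameter walk."""

    def __init__(self):
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "_params", {})

    def __setattr__(self, key, value):
        if isinstance(value, Module):
            self._children[key] = value
        elif isinstance(value, Parameter):
            self._params[key] = value
        object.__setattr__(self, key, value)

    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield (f"{prefix}{k}" if not p.name else f"{prefix}{p.name}"), p
        for k, c in self._children.items():
            yield from c.named_parameters(prefix=f"{prefix}{k}.")

    def parameters(self, trainable_only=False):
        for _, p in self.named_parameters():
            if not trainable_only or p.trainable:
                yield p

    def count_parameters(self):
        """(total, trainable, non_trainable) weight-element counts."""
        tr = sum(p.data.size for p in self.parameters() if p.trainable)
        nt = sum(p.data.size for p in self.parameters() if not p.trainable)
        return tr + nt, tr, nt

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing weight: {name}")
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape}, model {p.data.shape}"
                )
            p.data[...] = arr


# ---------------------------------------------------------------------------
# layers


class Conv2D(Module):
    def __init__(self, cin, cout, k, rng, stride=1, dilation=1, padding="same",
                 use_bias=True, dtype=np.float32):
        super().__init__()
        fan_in = k * k * cin
        std = np.sqrt(2.0 / fan_in)  # He-normal
        self.w = Parameter(rng.normal(0.0, std, (k, k, cin, cout)).astype(dtype), "w")
        self.b = Parameter(np.zeros(cout, dtype=dtype), "b") if use_bias else None
        self.stride, self.dilation, self.padding = stride, dilation, padding

    def __call__(self, x):
        return conv2d(x, self.w, self.b, self.stride, self.dilation, self.padding)


class DepthwiseConv2D(Module):
    def __init__(self, c, k, rng, stride=1, dilation=1, padding="same", dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / (k * k))
        self.w = Parameter(rng.normal(0.0, std, (k, k, c)).astype(dtype), "w")
        self.stride, self.dilation, self.padding = stride, dilation, padding

    def __call__(self, x):
        return depthwise_conv2d(x, self.w, self.stride, self.dilation, self.padding)


class BatchNorm(Module):
    def __init__(self, c, momentum=0.9, eps=1e-3, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=dtype), "gamma")
        self.beta = Parameter(np.zeros(c, dtype=dtype), "beta")
        self.moving_mean = Parameter(np.zeros(c, dtype=dtype), "moving_mean", trainable=False)
        self.moving_var = Parameter(np.ones(c, dtype=dtype), "moving_var", trainable=False)
        self.momentum, self.eps = momentum, eps
        self.training = False

    def __call__(self, x):
        return batch_norm(x, self.gamma, self.beta, self.moving_mean, self.moving_var,
                          self.training, self.momentum, self.eps)


def set_training(module, flag):
    """Switch every BatchNorm under ``module`` to train/inference mode."""
    if isinstance(module, BatchNorm):
        module.training = flag
    for child in module._children.values():
        set_training(child, flag)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
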