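"""Parameter-free SimAM attention.

SimAM scores every activation by its squared deviation from the spatial
mean of its channel, normalized by the channel variance, and rescales the
feature map by the sigmoid of that importance score:

    u     = mean over (H, W) of X, per sample and channel
    d     = (X - u)^2
    v     = sum(d) / (H*W - 1)            (channel variance)
    E_inv = d / (4 * max(v, lam) + 0.5)
    out   = X * sigmoid(E_inv)

No learnable weights are introduced.  A spatially constant map has d = 0
everywhere, so the output is exactly 0.5 * X; any non-constant map is
scaled by factors in (0.5, 1).  The regularizer ``lam`` guards the
division for near-constant channels and defaults to 1e-7.
"""

from __future__ import annotations

import numpy as np

from . import _engine as eng
from ._engine import Tensor

__all__ = ["DEFAULT_LAMBDA", "ATTENTION_KINDS", "simam", "attach_attention"]

DEFAULT_LAMBDA = 1e-7

ATTENTION_KINDS = ("none", "simam")


def simam(x, lam=DEFAULT_LAMBDA):
    """Apply SimAM to an NHWC tensor (or ndarray); shape is preserved.

    Built from differentiable primitives, so gradients flow through the
    attention weights as well as the identity path.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x))
    n_, h, w, c_ = x.shape
    n = h * w - 1
    if n < 1:
        raise ValueError("SimAM needs at least two spatial positions (H*W >= 2)")
    u = eng.reduce_mean(x, axis=(1, 2), keepdims=True)
    d = eng.square(eng.sub(x, u))
    v = eng.div(eng.reduce_sum(d, axis=(1, 2), keepdims=True), Tensor(np.asarray(float(n), dtype=x.dtype)))
    denom = eng.maximum_scalar(v, lam)
    four = Tensor(np.asarray(4.0, dtype=x.dtype))
    half = Tensor(np.asarray(0.5, dtype=x.dtype))
    e_inv = eng.div(d, eng.add(eng.mul(four, denom), half))
    return eng.mul(x, eng.sigmoid(e_inv))


def simam_reference(x, lam=DEFAULT_LAMBDA):
    """Straightforward ndarray evaluation of the SimAM formula.

    Used as the cross-check oracle in tests; keeps no tape.
    """
    x = np.asarray(x, dtype=np.float64)
    h, w = x.shape[1], x.shape[2]
    u = x.mean(axis=(1, 2), keepdims=True)
    d = (x - u) ** 2
    v = d.sum(axis=(1, 2), keepdims=True) / (h * w - 1)
    e_inv = d / (4.0 * np.maximum(v, lam) + 0.5)
    return x * (1.0 / (1.0 + np.exp(-e_inv)))


def attach_attention(pyramid, kind="simam", lam=DEFAULT_LAMBDA):
    """Apply the selected attention after each tapped backbone layer.

    ``kind='none'`` returns the pyramid unchanged; ``'simam'`` wraps each
    of low/middle/deep.  Either way the model gains zero parameters.
    """
    if kind == "none":
        return pyramid
    if kind == "simam":
        from .backbone import FeaturePyramid

        return FeaturePyramid(
            low=simam(pyramid.low, lam),
            middle=simam(pyramid.middle, lam),
            deep=simam(pyramid.deep, lam),
        )
    raise ValueError(f"unknown attention kind {kind!r}; expected one of {ATTENTION_KINDS}")
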