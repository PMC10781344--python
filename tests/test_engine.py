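"""Gradient and equivalence checks for the autodiff engine.

Every differentiable op is verified against central finite differences on
small float64 problems; the fused conv+BN+ReLU path is additionally
checked for exact agreement with its unfused composition.
"""

import numpy as np
import pytest

import midseg._engine as eng
from midseg._engine import Parameter, Tensor


def _fd_grad(f, arr, eps=1e-6):
    """Central finite-difference gradient of scalar f wrt arr."""
    g = np.zeros_like(arr)
    flat = arr.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        hi = f()
        flat[i] = old - eps
        lo = f()
        flat[i] = old
        gf[i] = (hi - lo) / (2 * eps)
    return g


def _check_grads(build_loss, tensors, rtol=1e-5, atol=5e-6):
    """Autodiff vs finite differences for every tensor in the list."""
    loss = build_loss()
    loss.backward()
    grads = []
    for t in tensors:
        assert t.grad is not None, "no gradient reached a differentiated input"
        grads.append(t.grad.copy())
    for t, g in zip(tensors, grads):
        fd = _fd_grad(lambda: float(build_loss().data), t.data)
        np.testing.assert_allclose(g, fd, rtol=rtol, atol=atol)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "k,stride,dilation,padding,bias",
    [
        (1, 1, 1, "valid", True),
        (1, 2, 1, "valid", False),
        (3, 1, 1, "same", True),
        (3, 1, 2, "same", False),
        (3, 2, 1, ((1, 1), (1, 1)), True),
        (7, 2, 1, ((3, 3), (3, 3)), False),
    ],
)
def test_conv2d_gradients(rng, k, stride, dilation, padding, bias):
    x = Tensor(rng.normal(size=(2, 8, 8, 3)), requires_grad=True)
    w = Parameter(rng.normal(size=(k, k, 3, 4)))
    b = Parameter(rng.normal(size=4)) if bias else None

    def loss():
        x.grad = w.grad = None
        if b is not None:
            b.grad = None
        y = eng.conv2d(x, w, b, stride=stride, dilation=dilation, padding=padding)
        return eng.reduce_sum(eng.square(y), axis=(0, 1, 2, 3), keepdims=False)

    _check_grads(loss, [x, w] + ([b] if bias else []))


def test_depthwise_conv_gradients(rng):
    x = Tensor(rng.normal(size=(2, 6, 6, 4)), requires_grad=True)
    w = Parameter(rng.normal(size=(3, 3, 4)))

    def loss():
        x.grad = w.grad = None
        y = eng.depthwise_conv2d(x, w, dilation=2)
        return eng.reduce_sum(eng.square(y), axis=(0, 1, 2, 3), keepdims=False)

    _check_grads(loss, [x, w])


@pytest.mark.parametrize("training", [True, False])
def test_batch_norm_gradients(rng, training):
    c = 3
    x = Tensor(rng.normal(size=(2, 4, 4, c)), requires_grad=True)
    gamma = Parameter(rng.normal(size=c) + 2.0)
    beta = Parameter(rng.normal(size=c))
    mm = Parameter(rng.normal(size=c), trainable=False)
    mv = Parameter(rng.random(c) + 0.5, trainable=False)

    def loss():
        x.grad = gamma.grad = beta.grad = None
        mm_c = Parameter(mm.data.copy(), trainable=False)
        mv_c = Parameter(mv.data.copy(), trainable=False)
        y = eng.batch_norm(x, gamma, beta, mm_c, mv_c, training=training)
        return eng.reduce_sum(eng.square(y), axis=(0, 1, 2, 3), keepdims=False)

    _check_grads(loss, [x, gamma, beta], rtol=1e-4, atol=1e-6)


def test_conv_bn_act_matches_unfused(rng):
    """Fused conv+BN+ReLU equals conv2d -> batch_norm -> relu exactly."""
    x = Tensor(rng.normal(size=(2, 6, 6, 3)))
    w = Parameter(rng.normal(size=(3, 3, 3, 5)))
    b = Parameter(rng.normal(size=5))
    gamma = Parameter(rng.normal(size=5) + 2.0)
    beta = Parameter(rng.normal(size=5))
    for training in (True, False):
        mm1, mv1 = Parameter(np.zeros(5), trainable=False), Parameter(np.ones(5), trainable=False)
        mm2, mv2 = Parameter(np.zeros(5), trainable=False), Parameter(np.ones(5), trainable=False)
        fused = eng.conv_bn_act(x, w, gamma, beta, mm1, mv1, training, b=b)
        ref = eng.relu(eng.batch_norm(eng.conv2d(x, w, b), gamma, beta, mm2, mv2, training))
        np.testing.assert_allclose(fused.data, ref.data, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(mm1.data, mm2.data, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(mv1.data, mv2.data, rtol=1e-8, atol=1e-12)


@pytest.mark.parametrize("training", [True, False])
@pytest.mark.parametrize("act", ["relu", None])
def test_conv_bn_act_gradients(rng, training, act):
    x = Tensor(rng.normal(size=(2, 5, 5, 3)), requires_grad=True)
    w = Parameter(rng.normal(size=(3, 3, 3, 4)))
    b = Parameter(rng.normal(size=4))
    gamma = Parameter(rng.normal(size=4) + 2.0)
    beta = Parameter(rng.normal(size=4))

    def loss():
        for t in (x, w, b, gamma, beta):
            t.grad = None
        mm = Parameter(np.zeros(4), trainable=False)
        mv = Parameter(np.ones(4), trainable=False)
        y = eng.conv_bn_act(x, w, gamma, beta, mm, mv, training, b=b, act=act)
        # smooth losses only: square of relu output is differentiable a.e.
        return eng.reduce_sum(eng.square(y), axis=(0, 1, 2, 3), keepdims=False)

    tensors = [x, w, gamma, beta] + ([] if training else [b])
    _check_grads(loss, tensors, rtol=1e-4, atol=1e-6)
    if training:
        # a bias feeding a train-mode BN is absorbed by the mean
        # subtraction: its gradient must be exactly zero
        l = loss()
        l.backward()
        np.testing.assert_allclose(b.grad, 0.0, atol=1e-9)


def test_max_pool_gradients(rng):
    x = Tensor(rng.normal(size=(2, 7, 7, 3)), requires_grad=True)

    def loss():
        x.grad = None
        y = eng.max_pool2d(x, pool=3, stride=2, padding=((1, 1), (1, 1)))
        return eng.reduce_sum(eng.square(y), axis=(0, 1, 2, 3), keepdims=False)

    _check_grads(loss, [x])


def test_resize_bilinear_gradients_and_matrix_oracle(rng):
    x = Tensor(rng.normal(size=(1, 3, 4, 2)), requires_grad=True)
    y = eng.resize_bilinear(x, 6, 8)
    # forward agrees with the dense interpolation-matrix formulation
    lh = eng.bilinear_matrix(6, 3)
    lw = eng.bilinear_matrix(8, 4)
    ref = np.einsum("oh,nhwc,pw->nopc", lh, x.data, lw)
    np.testing.assert_allclose(y.data, ref, rtol=1e-12, atol=1e-12)

    def loss():
        x.grad = None
        z = eng.resize_bilinear(x, 6, 8)
        return eng.reduce_sum(eng.square(z), axis=(0, 1, 2, 3), keepdims=False)

    _check_grads(loss, [x])


def test_resize_bilinear_downsample_and_identity(rng):
    x = Tensor(rng.normal(size=(1, 8, 8, 3)))
    same = eng.resize_bilinear(x, 8, 8)
    np.testing.assert_allclose(same.data, x.data, atol=1e-12)
    down = eng.resize_bilinear(x, 4, 4)
    assert down.shape == (1, 4, 4, 3)
    # 1x1 source broadcasts
    one = eng.resize_bilinear(Tensor(np.full((1, 1, 1, 2), 3.0)), 5, 5)
    np.testing.assert_allclose(one.data, 3.0)


def test_softmax_cross_entropy_gradient(rng):
    logits = Tensor(rng.normal(size=(2, 3, 3, 4)), requires_grad=True)
    labels = rng.integers(0, 4, size=(2, 3, 3))

    def loss():
        logits.grad = None
        return eng.softmax_cross_entropy(logits, labels)

    _check_grads(loss, [logits], rtol=1e-5, atol=1e-8)


def test_elementwise_broadcast_gradients(rng):
    a = Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)
    b = Tensor(rng.normal(size=(1, 1, 4)) + 2.0, requires_grad=True)

    def loss():
        a.grad = b.grad = None
        y = eng.div(eng.mul(eng.add(a, b), eng.sub(a, b)), b)
        z = eng.maximum_scalar(eng.sigmoid(y), 0.3)
        return eng.reduce_sum(eng.square(z), axis=(0, 1, 2), keepdims=False)

    _check_grads(loss, [a, b], rtol=1e-4, atol=1e-7)


def test_concat_and_add_relu_gradients(rng):
    a = Tensor(rng.normal(size=(1, 2, 2, 3)), requires_grad=True)
    b = Tensor(rng.normal(size=(1, 2, 2, 2)), requires_grad=True)
    c = Tensor(rng.normal(size=(1, 2, 2, 5)), requires_grad=True)

    def loss():
        a.grad = b.grad = c.grad = None
        y = eng.concat([a, b], axis=-1)
        z = eng.add_relu(y, c)
        return eng.reduce_sum(eng.square(z), axis=(0, 1, 2, 3), keepdims=False)

    _check_grads(loss, [a, b, c])


def test_no_grad_builds_no_tape(rng):
    x = Tensor(rng.normal(size=(1, 4, 4, 3)), requires_grad=True)
    w = Parameter(rng.normal(size=(3, 3, 3, 2)))
    with eng.no_grad():
        y = eng.conv2d(x, w)
    assert y._backward is None and y._parents == ()


def test_adam_converges_on_quadratic(rng):
    p = Parameter(np.array([5.0, -3.0]))
    opt = eng.Adam([p], lr=0.1)
    for _ in range(400):
        p.grad = 2 * (p.data - np.array([1.0, 2.0]))
        opt.step()
        opt.zero_grad()
    np.testing.assert_allclose(p.data, [1.0, 2.0], atol=1e-3)
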