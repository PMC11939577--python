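"""Finite-difference checks of every backward rule the network relies on."""

import numpy as np
import pytest

from lusseg.autograd import Tensor, concatenate


def numeric_grad(fn, x: np.ndarray, h: float = 1e-2) -> np.ndarray:
    """Central finite differences of a scalar-valued fn of one array."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        fp = fn(x)
        flat[i] = orig - h
        fm = fn(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * h)
    return g


def check_grad(make_output, x0: np.ndarray, rtol: float = 2e-2,
               atol: float = 5e-3) -> None:
    t = Tensor(x0.astype(np.float32), requires_grad=True)
    out = make_output(t)
    out.sum().backward()
    analytic = t.grad.astype(np.float64)

    def scalar(arr):
        return float(make_output(Tensor(arr.astype(np.float32))).data.sum())

    numeric = numeric_grad(scalar, x0.copy())
    np.testing.assert_allclose(analytic, numeric, rtol=rtol, atol=atol)


@pytest.mark.parametrize("op", [
    lambda t: t * 3.0 + 1.5,
    lambda t: (t * t).sum(axis=1) - t.mean(axis=1),
    lambda t: t / (t * t + 2.0),
    lambda t: t.relu() + t.sigmoid(),
    lambda t: t.gelu(),
    lambda t: (t + 3.0).log() * (0.1 * t).exp(),
    lambda t: t.softmax(axis=-1) * Tensor(np.arange(12.0).reshape(3, 4)),
    lambda t: t.reshape(2, 6).transpose(1, 0)[2:5, :],
    lambda t: t.clip(-0.5, 0.5),
    lambda t: concatenate([t, t * 2.0], axis=0),
    lambda t: t.broadcast_to((5, 3, 4)).sum(axis=0) * t,
], ids=["affine", "reductions", "division", "relu_sigmoid", "gelu",
        "log_exp", "softmax", "reshape_transpose_slice", "clip", "concat",
        "broadcast"])
def test_elementwise_and_shape_ops(rng, op):
    x = rng.standard_normal((3, 4))
    check_grad(op, x)


def test_matmul_grads(rng):
    a0 = rng.standard_normal((4, 5))
    b0 = rng.standard_normal((5, 3)).astype(np.float32)
    check_grad(lambda t: t @ Tensor(b0), a0)
    # gradient w.r.t. the right operand, and batched matmul
    a_const = Tensor(rng.standard_normal((2, 3, 5)).astype(np.float32))
    check_grad(lambda t: a_const @ t.reshape(5, 3), rng.standard_normal((5, 3)))


def test_layer_norm_grad(rng):
    w = Tensor(rng.standard_normal(6).astype(np.float32), requires_grad=True)
    b = Tensor(rng.standard_normal(6).astype(np.float32), requires_grad=True)
    x0 = rng.standard_normal((4, 6))
    check_grad(lambda t: t.layer_norm(w, b), x0)
    # parameter gradients (reset accumulation from the input-grad check)
    w.grad = b.grad = None
    x = Tensor(x0.astype(np.float32))
    out = x.layer_norm(w, b)
    out.sum().backward()
    assert w.grad is not None and b.grad is not None
    np.testing.assert_allclose(b.grad, np.full(6, 4.0), rtol=1e-5)


def test_conv2d_grads(rng):
    w = Tensor(rng.standard_normal((3, 2, 3, 3)).astype(np.float32) * 0.3,
               requires_grad=True)
    b = Tensor(np.zeros(3, dtype=np.float32), requires_grad=True)
    x0 = rng.standard_normal((2, 2, 5, 5))
    check_grad(lambda t: t.conv2d(w, b, padding=1), x0)
    # weight gradient via finite differences
    w.grad = b.grad = None
    x = Tensor(x0.astype(np.float32))
    w0 = w.data.copy()

    def loss_of_w(warr):
        return float(x.conv2d(Tensor(warr.astype(np.float32)), b,
                              padding=1).data.sum())

    out = x.conv2d(w, b, padding=1)
    out.sum().backward()
    numeric = numeric_grad(loss_of_w, w0.copy())
    np.testing.assert_allclose(w.grad, numeric, rtol=2e-2, atol=5e-3)


def test_conv2d_matches_direct_convolution(rng):
    """Cross-check the GEMM formulation against an explicit loop."""
    x = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
    w = rng.standard_normal((3, 2, 3, 3)).astype(np.float32)
    out = Tensor(x).conv2d(Tensor(w), None, padding=1).data
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    ref = np.zeros((1, 3, 6, 6))
    for co in range(3):
        for ci in range(2):
            for i in range(3):
                for j in range(3):
                    ref[0, co] += w[co, ci, i, j] * xp[0, ci, i:i + 6, j:j + 6]
    np.testing.assert_allclose(out, ref, rtol=1e-4, atol=1e-5)


def test_upsample2x_grad(rng):
    check_grad(lambda t: t.upsample2x() * 0.5, rng.standard_normal((1, 2, 3, 3)))


def test_batch_norm_grad(rng):
    w = Tensor(rng.standard_normal(3).astype(np.float32), requires_grad=True)
    b = Tensor(np.zeros(3, dtype=np.float32), requires_grad=True)
    rm, rv = np.zeros(3, np.float32), np.ones(3, np.float32)
    x0 = rng.standard_normal((2, 3, 4, 4))
    check_grad(lambda t: (t.batch_norm(w, b, rm.copy(), rv.copy(),
                                       training=True) * 0.3).sum(axis=1), x0)


def test_backward_accumulates_through_shared_nodes(rng):
    x = Tensor(np.array([2.0]), requires_grad=True)
    y = x * x + x * 3.0  # dy/dx = 2x + 3 = 7
    y.sum().backward()
    np.testing.assert_allclose(x.grad, [7.0], rtol=1e-6)
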