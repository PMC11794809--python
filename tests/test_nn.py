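"""Layer-level checks: shapes, analytic gradients vs finite differences."""

import numpy as np
import pytest

from mseegnet import nn

RNG = np.random.default_rng(42)


def numeric_grad(f, x, eps=1e-3):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def check_layer_grads(layer, x, train=True, rng=None, atol=2e-2):
    """Analytic input+parameter grads match finite differences."""
    def loss():
        y = layer.forward(x, train=train, rng=rng)
        return float((np.sin(np.arange(y.size).reshape(y.shape) * 0.1) * y).sum())

    w_out = np.sin(np.arange(layer.forward(x, train=train, rng=rng).size) * 0.1)
    y = layer.forward(x, train=train, rng=rng)
    dy = w_out.reshape(y.shape).astype(np.float32)
    for p in layer.params():
        p.zero_grad()
    dx = layer.backward(dy)

    gx = numeric_grad(loss, x)
    assert np.allclose(dx, gx, atol=atol), f"input grad mismatch {np.abs(dx-gx).max()}"
    for j, p in enumerate(layer.params()):
        layer.forward(x, train=train, rng=rng)  # refresh caches
        gp = numeric_grad(loss, p.data)
        assert np.allclose(p.grad, gp, atol=atol), (
            f"param {j} grad mismatch {np.abs(p.grad - gp).max()}")


@pytest.mark.parametrize("kernel", [1, 3, 4, 8])
def test_temporal_conv_gradients(kernel):
    layer = nn.TemporalConv(3, kernel, np.random.default_rng(0))
    x = RNG.standard_normal((2, 1, 4, 12)).astype(np.float32)
    check_layer_grads(layer, x)


def test_temporal_conv_matches_direct_convolution():
    """Same-padded output equals a nested-loop cross-correlation oracle."""
    rng = np.random.default_rng(3)
    layer = nn.TemporalConv(2, 5, rng)
    x = rng.standard_normal((1, 1, 3, 10)).astype(np.float32)
    y = layer.forward(x)
    k = 5
    pl = (k - 1) // 2
    w = layer.w.data
    for f in range(2):
        for c in range(3):
            for t in range(10):
                acc = 0.0
                for j in range(k):
                    src = t - pl + j
                    if 0 <= src < 10:
                        acc += w[f, j] * x[0, 0, c, src]
                assert abs(y[0, f, c, t] - acc) < 1e-4


def test_temporal_conv_delta_impulse_recovers_kernel():
    rng = np.random.default_rng(1)
    layer = nn.TemporalConv(1, 3, rng)
    x = np.zeros((1, 1, 1, 9), dtype=np.float32)
    x[0, 0, 0, 4] = 1.0
    y = layer.forward(x)[0, 0, 0]
    # cross-correlation convention: an impulse reproduces the kernel reversed
    w = layer.w.data[0]
    assert np.allclose(y[3:6], w[::-1], atol=1e-6)


def test_temporal_conv_rejects_oversized_kernel():
    layer = nn.TemporalConv(2, 64, np.random.default_rng(0))
    with pytest.raises(ValueError, match="exceeds"):
        layer.forward(np.zeros((1, 1, 3, 16), dtype=np.float32))


@pytest.mark.parametrize("train", [True, False])
def test_batchnorm_gradients(train):
    layer = nn.BatchNorm(3)
    layer.running_mean = np.array([0.1, -0.2, 0.3], dtype=np.float32)
    layer.running_var = np.array([1.1, 0.7, 1.4], dtype=np.float32)
    x = RNG.standard_normal((3, 3, 2, 5)).astype(np.float32)
    check_layer_grads(layer, x, train=train)


def test_batchnorm_rows_equals_stack_layout():
    """The 2-D rows fast path computes the same normalization as 4-D."""
    x = RNG.standard_normal((4, 3, 2, 6)).astype(np.float32)
    bn4 = nn.BatchNorm(3)
    y4 = bn4.forward(x, train=True)
    rows = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(3, -1)
    bn2 = nn.BatchNorm(3)
    y2 = bn2.forward(rows, train=True)
    back = y2.reshape(3, 4, 2, 6).transpose(1, 0, 2, 3)
    assert np.allclose(y4, back, atol=1e-5)
    assert np.allclose(bn4.running_mean, bn2.running_mean, atol=1e-6)
    assert np.allclose(bn4.running_var, bn2.running_var, atol=1e-5)


def test_depthwise_spatial_conv_gradients():
    layer = nn.DepthwiseSpatialConv(2, 2, 4, np.random.default_rng(0),
                                    max_norm=None)
    x = RNG.standard_normal((2, 2, 4, 6)).astype(np.float32)
    check_layer_grads(layer, x)


def test_depthwise_spatial_conv_sums_channels():
    """A unit filter (D=1) reduces an all-ones input to the electrode count."""
    layer = nn.DepthwiseSpatialConv(1, 1, 5, np.random.default_rng(0),
                                    max_norm=None)
    layer.w.data[...] = 1.0
    x = np.ones((2, 1, 5, 7), dtype=np.float32)
    y = layer.forward(x)
    assert y.shape == (2, 1, 1, 7)
    assert np.allclose(y, 5.0)


def test_depthwise_spatial_maxnorm_constrains_filters():
    layer = nn.DepthwiseSpatialConv(2, 2, 4, np.random.default_rng(0),
                                    max_norm=1.0)
    layer.w.data *= 10.0
    layer.constrain()
    norms = np.linalg.norm(layer.w.data, axis=2)
    assert np.all(norms <= 1.0 + 1e-5)


def test_depthwise_temporal_conv_gradients():
    layer = nn.DepthwiseTemporalConv(3, 4, np.random.default_rng(0))
    x = RNG.standard_normal((2, 3, 1, 10)).astype(np.float32)
    check_layer_grads(layer, x)


def test_pointwise_conv_identity_passthrough():
    layer = nn.PointwiseConv(3, 3, np.random.default_rng(0))
    layer.w.data[...] = np.eye(3, dtype=np.float32)
    x = RNG.standard_normal((2, 3, 1, 8)).astype(np.float32)
    assert np.allclose(layer.forward(x), x, atol=1e-6)


def test_separable_composition_matches_two_step_oracle():
    """Depthwise-then-pointwise equals the explicit nested-loop composition."""
    rng = np.random.default_rng(7)
    dw = nn.DepthwiseTemporalConv(3, 5, rng)
    pw = nn.PointwiseConv(3, 2, rng)
    x = rng.standard_normal((2, 3, 1, 9)).astype(np.float32)
    y = pw.forward(dw.forward(x))
    k, pl = 5, 2
    mid = np.zeros((2, 3, 9))
    for b in range(2):
        for m in range(3):
            for t in range(9):
                for j in range(k):
                    src = t - pl + j
                    if 0 <= src < 9:
                        mid[b, m, t] += dw.w.data[m, j] * x[b, m, 0, src]
    ref = np.einsum("fm,bmt->bft", pw.w.data, mid)
    assert np.allclose(y[:, :, 0, :], ref, atol=1e-5)


def test_pointwise_conv_gradients():
    layer = nn.PointwiseConv(3, 2, np.random.default_rng(0))
    x = RNG.standard_normal((2, 3, 1, 7)).astype(np.float32)
    check_layer_grads(layer, x)


def test_elu_gradients():
    x = RNG.standard_normal((2, 3, 2, 5)).astype(np.float32)
    check_layer_grads(nn.ELU(), x)


def test_avgpool_shape_and_gradients():
    layer = nn.AvgPoolTime(3)
    x = RNG.standard_normal((2, 2, 1, 10)).astype(np.float32)
    y = layer.forward(x)
    assert y.shape == (2, 2, 1, 3)     # floor(10/3), ragged tail dropped
    check_layer_grads(layer, x)


def test_dropout_eval_is_identity_and_train_scales():
    layer = nn.Dropout(0.5)
    x = np.ones((4, 3, 1, 100), dtype=np.float32)
    assert layer.forward(x, train=False) is x
    y = layer.forward(x, train=True, rng=np.random.default_rng(0))
    kept = y[y > 0]
    assert np.allclose(kept, 2.0)      # inverted dropout rescale
    assert 0.3 < (y > 0).mean() < 0.7


def test_dense_gradients_and_maxnorm():
    layer = nn.Dense(5, 3, np.random.default_rng(0), max_norm=0.25)
    x = RNG.standard_normal((4, 5)).astype(np.float32)
    check_layer_grads(layer, x)
    layer.w.data *= 100
    layer.constrain()
    assert np.all(np.linalg.norm(layer.w.data, axis=0) <= 0.25 + 1e-6)


def test_eca_gate_gradients():
    layer = nn.ECAGate(5, 3, np.random.default_rng(0))
    x = RNG.standard_normal((2, 5, 1, 6)).astype(np.float32)
    check_layer_grads(layer, x)


def test_softmax_cross_entropy_gradient():
    logits = RNG.standard_normal((5, 4)).astype(np.float32)
    labels = np.array([0, 1, 2, 3, 1])
    loss, dlogits, probs = nn.softmax_cross_entropy(logits, labels)
    eps = 1e-4
    for i in (0, 3):
        for j in range(4):
            lp = logits.copy(); lp[i, j] += eps
            lm = logits.copy(); lm[i, j] -= eps
            num = (nn.softmax_cross_entropy(lp, labels)[0]
                   - nn.softmax_cross_entropy(lm, labels)[0]) / (2 * eps)
            assert abs(num - dlogits[i, j]) < 1e-3
    assert np.allclose(probs.sum(axis=1), 1.0)
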