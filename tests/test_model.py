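"""Architecture contracts: ECA formulas, fusion wiring, shapes, checkpoints."""

import numpy as np
import pytest

from mseegnet import nn
from mseegnet.model import (BranchSpec, ModelConfig, MultiscaleEEGNet,
                            eca_kernel_size, fuse, load_checkpoint,
                            parameter_count, save_checkpoint)


# --------------------------------------------------------------- ECA kernel

@pytest.mark.parametrize("c_maps,gamma,b,expected", [
    (32, 2.0, 1.0, 3),      # (5+1)/2 = 3
    (16, 2.0, 1.0, 3),      # (4+1)/2 = 2.5 -> nearest odd, ties up
    (1, 2.0, 1.0, 1),       # floor at 1
    (8, 2.0, 1.0, 1),       # (3+1)/2 = 2 -> tie -> up? lower 1, upper 3, tie -> 3
])
def test_eca_kernel_size(c_maps, gamma, b, expected):
    if (c_maps, expected) == (8, 1):
        # (3+1)/2 = 2 is equidistant from 1 and 3; ties round up
        assert eca_kernel_size(c_maps, gamma, b) == 3
    else:
        assert eca_kernel_size(c_maps, gamma, b) == expected


def test_eca_kernel_size_is_odd_and_positive():
    for c in range(1, 200):
        k = eca_kernel_size(c)
        assert k >= 1 and k % 2 == 1


# ---------------------------------------------------------------- ECA block

def eca_oracle(x, kernel, bias):
    """Nested-loop evaluation: GAP -> 1D same-pad conv -> sigmoid -> rescale."""
    b, m, s, t = x.shape
    k = len(kernel)
    pad = k // 2
    out = np.zeros_like(x, dtype=np.float64)
    for bi in range(b):
        z = np.array([x[bi, mi].mean() for mi in range(m)])
        for mi in range(m):
            acc = bias
            for j in range(k):
                src = mi - pad + j
                if 0 <= src < m:
                    acc += kernel[j] * z[src]
            gate = 1.0 / (1.0 + np.exp(-acc))
            out[bi, mi] = x[bi, mi] * gate
    return out


def test_eca_matches_nested_loop_oracle_on_many_stacks():
    """Vectorized ECA equals the elementwise oracle on >= 50 random stacks."""
    rng = np.random.default_rng(0)
    for trial in range(60):
        b = int(rng.integers(1, 5))
        m = int(rng.integers(1, 9))
        t = int(rng.integers(1, 33))
        k = int(rng.choice([1, 3, 5]))
        x = rng.standard_normal((b, m, 1, t)).astype(np.float32)
        kernel = rng.standard_normal(k).astype(np.float32)
        bias = float(rng.standard_normal())
        got, _, _ = nn.eca_attention(x, kernel, bias)
        want = eca_oracle(x, kernel, bias)
        assert np.allclose(got, want, atol=1e-5), f"mismatch at trial {trial}"


def test_eca_equal_means_give_one_common_interior_gate():
    """Equal map means collapse the interior gates to one scalar.

    (Zero "same" padding makes the two edge maps see missing neighbours,
    so the symmetry argument applies to interior maps.)
    """
    x = np.full((2, 6, 1, 8), 0.7, dtype=np.float32)
    gated, _, gates = nn.eca_attention(x, np.array([0.3, -0.2, 0.5]), 0.1)
    interior = gates[:, 1:-1]
    assert np.allclose(interior, interior[:, :1])
    assert np.allclose(gated[:, 1:-1], interior[0, 0] * x[:, 1:-1], atol=1e-6)


def test_eca_zero_kernel_halves_input():
    x = np.random.default_rng(0).standard_normal((2, 3, 1, 5)).astype(np.float32)
    gated, _, gates = nn.eca_attention(x, np.zeros(3), 0.0)
    assert np.allclose(gates, 0.5)
    assert np.allclose(gated, x / 2, atol=1e-6)


def test_eca_gates_in_open_unit_interval_and_shape_preserved():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((3, 6, 1, 10)).astype(np.float32) * 10
    gated, z, gates = nn.eca_attention(x, rng.standard_normal(3), 0.0)
    assert gated.shape == x.shape
    assert np.all((gates > 0) & (gates < 1))


def test_eca_gap_is_linear_in_input_scale():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((2, 4, 1, 7)).astype(np.float32)
    _, z1, _ = nn.eca_attention(x, np.ones(3), 0.0)
    _, z3, _ = nn.eca_attention(3 * x, np.ones(3), 0.0)
    assert np.allclose(z3, 3 * z1, atol=1e-5)


# -------------------------------------------------------------------- fuse

def test_fuse_concatenates_map_counts():
    a = np.random.default_rng(0).standard_normal((2, 4, 3, 8)).astype(np.float32)
    b = np.random.default_rng(1).standard_normal((2, 8, 3, 8)).astype(np.float32)
    f = fuse(a, b)
    assert f.shape == (2, 12, 3, 8)
    assert np.array_equal(f[:, :4], a)     # lossless: slicing recovers operands
    assert np.array_equal(f[:, 4:], b)


def test_fuse_empty_is_identity():
    a = np.ones((2, 4, 3, 8), dtype=np.float32)
    assert fuse(a, np.empty((2, 0, 3, 8))) is a


def test_fuse_rejects_mismatched_stages():
    a = np.zeros((2, 4, 3, 8))
    b = np.zeros((2, 8, 3, 9))
    with pytest.raises(ValueError, match="disagree"):
        fuse(a, b)


def test_fuse_depthwise_map_bookkeeping():
    a = np.zeros((1, 24, 1, 10))
    b = np.zeros((1, 32, 1, 10))
    assert fuse(a, b).shape[1] == 56


# ------------------------------------------------------------ architecture

def test_default_config_matches_doubling_rule():
    cfg = ModelConfig(n_electrodes=22, n_timesamples=1125, n_classes=4)
    f1 = [b.f1 for b in cfg.branches]
    ks = [b.kernel for b in cfg.branches]
    assert f1 == [4, 8, 16] and ks == [16, 32, 64]
    assert all(b.f2 == b.f1 * b.depth_mult for b in cfg.branches)


def test_forward_probability_simplex_and_fused_map_counts():
    cfg = ModelConfig(n_electrodes=22, n_timesamples=1125, n_classes=4)
    m = MultiscaleEEGNet(cfg, seed=0)
    assert m.dw_in == [4, 12, 16]          # branch-2 depthwise input fused
    assert m.sep_in == [8, 24, 56]         # branch-3 separable input fused
    x = np.random.default_rng(0).standard_normal((2, 22, 1125)).astype(np.float32)
    p = m.predict_proba(x)
    assert p.shape == (2, 4)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(p > 0)
    # softmax closed forms: uniform logits and the (1, 2) pair
    assert np.allclose(nn.softmax(np.zeros((1, 4))), 0.25)
    e = np.e
    assert np.allclose(nn.softmax(np.array([[1.0, 2.0]])),
                       [1 / (1 + e), e / (1 + e)], atol=1e-6)


def test_fusion_off_gives_independent_branches():
    cfg = ModelConfig(n_electrodes=10, n_timesamples=256, n_classes=2,
                      use_fusion=False, use_eca=False)
    m = MultiscaleEEGNet(cfg, seed=0)
    assert m.dw_in == [4, 8, 16]
    assert m.sep_in == [8, 16, 32]


def test_single_branch_is_canonical_eegnet_shapes():
    cfg = ModelConfig(n_electrodes=22, n_timesamples=1024, n_classes=4,
                      branches=[BranchSpec(f1=8, kernel=64, depth_mult=2)],
                      use_fusion=False, use_eca=False)
    m = MultiscaleEEGNet(cfg, seed=0)
    assert m.dw_in == [8] and m.dw_out == [16] and m.sep_in == [16]
    # canonical EEGNet time cascade: T/4 then /8
    assert m.branch_widths == [16 * ((1024 // 4) // 8)]
    x = np.zeros((1, 22, 1024), dtype=np.float32)
    assert m.predict_proba(x).shape == (1, 4)


def test_batch_permutation_equivariance():
    cfg = ModelConfig(n_electrodes=8, n_timesamples=256, n_classes=3)
    m = MultiscaleEEGNet(cfg, seed=1)
    x = np.random.default_rng(0).standard_normal((5, 8, 256)).astype(np.float32)
    p = m.predict_proba(x)
    perm = np.array([3, 0, 4, 1, 2])
    p2 = m.predict_proba(x[perm])
    assert np.allclose(p2, p[perm], atol=1e-5)


def test_forward_rejects_wrong_shape():
    cfg = ModelConfig(n_electrodes=8, n_timesamples=256, n_classes=2)
    m = MultiscaleEEGNet(cfg, seed=0)
    with pytest.raises(ValueError, match="does not match"):
        m.forward(np.zeros((1, 9, 256), dtype=np.float32))


def test_time_axis_alignment_at_fusion_points():
    """Equal pooling across branches keeps fusion operands time-aligned."""
    cfg = ModelConfig(n_electrodes=22, n_timesamples=1125, n_classes=4)
    m = MultiscaleEEGNet(cfg, seed=0)
    x = np.zeros((1, 22, 1125), dtype=np.float32)
    m.forward(x)
    t1 = m.activation_tap("temporal_1").shape[-1]
    t2 = m.activation_tap("temporal_2").shape[-1]
    assert t1 == t2 == 1125


# --------------------------------------------------------- parameter count

def test_parameter_count_head_closed_form():
    cfg = ModelConfig(n_electrodes=22, n_timesamples=1125, n_classes=4)
    m = MultiscaleEEGNet(cfg, seed=0)
    w = m.flat_width
    head = (w + 1) * 32 + 33 * 4
    assert (m.dense1.w.data.size + m.dense1.b.data.size
            + m.dense2.w.data.size + m.dense2.b.data.size) == head


def test_parameter_count_eca_contribution():
    base = dict(n_electrodes=10, n_timesamples=256, n_classes=2)
    with_eca = parameter_count(MultiscaleEEGNet(ModelConfig(**base), seed=0))
    no_eca = parameter_count(
        MultiscaleEEGNet(ModelConfig(**base, use_eca=False), seed=0))
    diff = with_eca - no_eca
    assert 0 < diff <= 3 * (3 + 1)     # k=3 kernel + bias per branch


def test_parameter_count_counts_every_weight():
    cfg = ModelConfig(n_electrodes=6, n_timesamples=128, n_classes=2)
    m = MultiscaleEEGNet(cfg, seed=0)
    assert parameter_count(m) == sum(p.data.size for p in m.params())


# --------------------------------------------------------------- persistence

def test_checkpoint_roundtrip(tmp_path):
    cfg = ModelConfig(n_electrodes=8, n_timesamples=256, n_classes=3)
    m = MultiscaleEEGNet(cfg, seed=3)
    x = np.random.default_rng(0).standard_normal((3, 8, 256)).astype(np.float32)
    p_before = m.predict_proba(x)
    path = tmp_path / "model.ckpt.npz"
    save_checkpoint(m, path)
    m2 = load_checkpoint(path)
    assert m2.config.to_dict() == cfg.to_dict()
    assert np.allclose(m2.predict_proba(x), p_before, atol=1e-7)


def test_same_seed_same_weights():
    cfg = ModelConfig(n_electrodes=8, n_timesamples=256, n_classes=2)
    a = MultiscaleEEGNet(cfg, seed=5)
    b = MultiscaleEEGNet(cfg, seed=5)
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa.data, pb.data)


def test_config_validation():
    with pytest.raises(ValueError, match="3 branches"):
        ModelConfig(n_electrodes=4, n_timesamples=64, n_classes=2,
                    branches=[BranchSpec(4, 16)], use_fusion=True)
    with pytest.raises(ValueError, match="odd"):
        ModelConfig(n_electrodes=4, n_timesamples=256, n_classes=2,
                    eca_k_override=4)
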