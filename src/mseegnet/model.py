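"""Multiscale EEGNet with fusion transmission and efficient channel attention.

The decoder runs three parallel EEGNet branches whose temporal filter counts
and kernel lengths double from branch to branch (F1 = 4/8/16, K = 16/32/64
samples), so the three branches see the input at three temporal scales.  Two
fusion links concatenate intermediate feature maps across branches: the
branch-1 temporal output joins branch-2's depthwise input, and the branch-2
depthwise output joins branch-3's separable input.  Each branch output is
gated by an efficient-channel-attention (ECA) block over its feature maps,
and a flatten -> dense(32) -> dense(n_classes) -> softmax head classifies.

Ablation switches (``use_fusion``, ``use_eca``) recover three independent
EEGNets; a single-branch config recovers the canonical EEGNet layer stack.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import DTYPE

__all__ = [
    "BranchSpec",
    "ModelConfig",
    "MultiscaleEEGNet",
    "eca_kernel_size",
    "fuse",
    "parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]


def eca_kernel_size(c_maps: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive ECA kernel width: nearest odd integer to (log2(C)+b)/gamma.

    Ties round up; the result is floored at 1.  With the defaults gamma=2,
    b=1 a 32-map stack gets k = 3.
    """
    if c_maps < 1:
        raise ValueError("c_maps must be >= 1")
    t = (math.log2(c_maps) + b) / gamma
    lower = 2 * math.floor((t - 1.0) / 2.0) + 1
    upper = lower + 2
    k = lower if (t - lower) < (upper - t) else upper
    return max(1, k)


def fuse(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fusion transmission: concatenate two feature stacks along the map axis.

    Both stacks must agree on batch, spatial and time axes; values are copied
    unchanged, so slicing the result recovers the operands exactly.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.ndim != 4 or b.ndim != 4:
        raise ValueError(f"fuse expects 4-axis stacks, got {a.shape} and {b.shape}")
    if b.shape[1] == 0:
        return a
    if a.shape[1] == 0:
        return b
    if (a.shape[0], a.shape[2], a.shape[3]) != (b.shape[0], b.shape[2], b.shape[3]):
        raise ValueError(
            f"fusion operands disagree outside the map axis: {a.shape} vs {b.shape}")
    return np.concatenate([a, b], axis=1)


@dataclass
class BranchSpec:
    """Hyperparameters of one EEGNet branch."""

    f1: int            # temporal filter count
    kernel: int        # temporal kernel length, samples
    depth_mult: int = 2
    f2: int | None = None   # separable output filters; defaults to f1 * depth_mult
    sep_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.25

    def __post_init__(self):
        if self.f2 is None:
            self.f2 = self.f1 * self.depth_mult
        if self.kernel < 1 or self.pool1 < 1 or self.pool2 < 1:
            raise ValueError("kernel and pool widths must be >= 1")


def default_branches() -> list[BranchSpec]:
    """The three stock branches: F1 and K double from one branch to the next."""
    return [BranchSpec(f1=4, kernel=16),
            BranchSpec(f1=8, kernel=32),
            BranchSpec(f1=16, kernel=64)]


@dataclass
class ModelConfig:
    """Everything needed to build the decoder for a (C, T) trial shape."""

    n_electrodes: int
    n_timesamples: int
    n_classes: int
    branches: list[BranchSpec] = field(default_factory=default_branches)
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    eca_k_override: int | None = 3
    dense_units: int = 32
    use_fusion: bool = True
    use_eca: bool = True
    temporal_batchnorm: bool = True
    max_norm: bool = True

    def __post_init__(self):
        self.branches = [b if isinstance(b, BranchSpec) else BranchSpec(**b)
                         for b in self.branches]
        if len(self.branches) not in (1, 3):
            raise ValueError("config needs 1 branch (canonical EEGNet) or 3")
        if len(self.branches) == 1 and self.use_fusion:
            raise ValueError("fusion transmission needs 3 branches")
        if self.dense_units < 1:
            raise ValueError("dense_units must be positive")
        if self.n_electrodes < 1 or self.n_timesamples < 1 or self.n_classes < 2:
            raise ValueError("invalid data shape / class count")
        if self.eca_k_override is not None and (
                self.eca_k_override < 1 or self.eca_k_override % 2 == 0):
            raise ValueError("eca_k_override must be a positive odd integer")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class _SeqStage:
    """A plain sequence of layers with shared forward/backward."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train, rng):
        for lay in self.layers:
            x = lay.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def iter_layers(self):
        return iter(self.layers)


class MultiscaleEEGNet:
    """The decoder network.  Weights are NumPy arrays; training is in-package.

    The temporal stage runs in a maps-major "rows" layout (maps, batch*C*T)
    so that batch-norm reductions and the fusion concatenation touch
    contiguous memory; the public 4-axis (batch, maps, spatial, time)
    contract is preserved at the layer level and in the activation taps.

    Parameters
    ----------
    config
        Architecture hyperparameters.
    seed
        Seeds weight initialization (Glorot-uniform) and, via
        :meth:`make_dropout_rng`, any dropout noise drawn during training.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        cfg = config
        nb = len(cfg.branches)
        C, T = cfg.n_electrodes, cfg.n_timesamples
        mn_dw = 1.0 if cfg.max_norm else None
        mn_dense = 0.25 if cfg.max_norm else None

        self.t_conv = [nn.TemporalConv(br.f1, br.kernel, rng) for br in cfg.branches]
        self.t_bn = [nn.BatchNorm(br.f1) if cfg.temporal_batchnorm else None
                     for br in cfg.branches]

        # fusion-aware input map counts
        self.dw_in = [br.f1 for br in cfg.branches]
        if cfg.use_fusion and nb == 3:
            self.dw_in[1] = cfg.branches[0].f1 + cfg.branches[1].f1
        self.dw_out = [m * br.depth_mult for m, br in zip(self.dw_in, cfg.branches)]

        self.dw_conv = []
        self.dw_tail = []
        for i, br in enumerate(cfg.branches):
            self.dw_conv.append(nn.DepthwiseSpatialConv(
                self.dw_in[i], br.depth_mult, C, rng, max_norm=mn_dw))
            self.dw_tail.append(_SeqStage([
                nn.BatchNorm(self.dw_out[i]),
                nn.ELU(),
                nn.AvgPoolTime(br.pool1),
                nn.Dropout(br.dropout),
            ]))

        self.sep_in = list(self.dw_out)
        if cfg.use_fusion and nb == 3:
            self.sep_in[2] = self.dw_out[1] + self.dw_out[2]

        self.separable = []
        for i, br in enumerate(cfg.branches):
            self.separable.append(_SeqStage([
                nn.DepthwiseTemporalConv(self.sep_in[i], br.sep_kernel, rng),
                nn.PointwiseConv(self.sep_in[i], br.f2, rng),
                nn.BatchNorm(br.f2),
                nn.ELU(),
                nn.AvgPoolTime(br.pool2),
                nn.Dropout(br.dropout),
            ]))

        self.eca = []
        if cfg.use_eca:
            for br in cfg.branches:
                k = (cfg.eca_k_override if cfg.eca_k_override is not None
                     else eca_kernel_size(br.f2, cfg.eca_gamma, cfg.eca_b))
                self.eca.append(nn.ECAGate(br.f2, k, rng))

        t_out = [(T // br.pool1) // br.pool2 for br in cfg.branches]
        if min(t_out) < 1:
            raise ValueError("time axis too short for the pooling cascade")
        self.branch_widths = [br.f2 * t for br, t in zip(cfg.branches, t_out)]
        self.flat_width = int(sum(self.branch_widths))

        self.dense1 = nn.Dense(self.flat_width, cfg.dense_units, rng,
                               max_norm=mn_dense)
        self.head_act = nn.ELU()
        self.dense2 = nn.Dense(cfg.dense_units, cfg.n_classes, rng,
                               max_norm=mn_dense)

        # forward-pass taps (rows layout) and backward-pass gradient taps
        self._rows_taps: dict[str, np.ndarray] = {}
        self._grad_rows_taps: dict[str, np.ndarray] = {}
        self.act_taps: dict[str, np.ndarray] = {}
        self._batch = None

    # ------------------------------------------------------------------ admin

    def params(self) -> list[nn.Param]:
        out = []
        for conv in self.t_conv:
            out.extend(conv.params())
        for bn in self.t_bn:
            if bn is not None:
                out.extend(bn.params())
        for conv, tail in zip(self.dw_conv, self.dw_tail):
            out.extend(conv.params())
            out.extend(tail.params())
        for stage in self.separable:
            out.extend(stage.params())
        for gate in self.eca:
            out.extend(gate.params())
        out.extend(self.dense1.params())
        out.extend(self.dense2.params())
        return out

    def layers(self):
        yield from self.t_conv
        for bn in self.t_bn:
            if bn is not None:
                yield bn
        for conv, tail in zip(self.dw_conv, self.dw_tail):
            yield conv
            yield from tail.iter_layers()
        for stage in self.separable:
            yield from stage.iter_layers()
        yield from self.eca
        yield self.dense1
        yield self.head_act
        yield self.dense2

    def constrain(self) -> None:
        for lay in self.layers():
            lay.constrain()

    def make_dropout_rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed + 0x5EED)

    def set_input_grad(self, flag: bool) -> None:
        """Toggle computing the gradient w.r.t. the raw input batch.

        Training never needs it (the temporal convs are the first layer);
        input-saliency analyses do.
        """
        for conv in self.t_conv:
            conv.input_grad = bool(flag)

    # ---------------------------------------------------------------- forward

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (batch, C, T) trials, got {x.shape}")
        cfg = self.config
        if x.shape[2] != cfg.n_electrodes or x.shape[3] != cfg.n_timesamples:
            raise ValueError(
                f"trial shape {x.shape[2:]} does not match the model\'s "
                f"(C={cfg.n_electrodes}, T={cfg.n_timesamples})")
        return np.ascontiguousarray(x)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                cols: list[np.ndarray] | None = None) -> np.ndarray:
        """Run the network; returns logits of shape (batch, n_classes).

        ``cols`` optionally supplies per-branch precomputed im2col matrices
        for this batch (the training loop builds them once per dataset, since
        they depend only on the trials, not on the weights).
        """
        x = self._check_input(x)
        cfg = self.config
        nb = len(cfg.branches)
        fusion = cfg.use_fusion and nb == 3
        b = x.shape[0]
        C, T = cfg.n_electrodes, cfg.n_timesamples
        self._batch = b

        rows = []
        for i in range(nb):
            r = self.t_conv[i]._forward_rows(
                x, col=None if cols is None else cols[i])
            if self.t_bn[i] is not None:
                r = self.t_bn[i].forward(r, train)
            rows.append(r)
            self._rows_taps[f"temporal_{i + 1}"] = r

        dw_rows = list(rows)
        if fusion:
            # fusion transmission 1 in rows layout: stack map-rows of the two
            # temporal outputs (same as fuse() on the 4-axis stacks)
            dw_rows[1] = np.concatenate([rows[0], rows[1]], axis=0)

        d_out = []
        for i in range(nb):
            x4 = dw_rows[i].reshape(self.dw_in[i], b, C, T)
            y4 = self.dw_conv[i]._forward_maps(x4)  # (M, B, D, T)
            y = np.ascontiguousarray(y4.transpose(1, 0, 2, 3)).reshape(
                b, self.dw_out[i], 1, T)
            d_out.append(self.dw_tail[i].forward(y, train, rng))

        sep_inputs = list(d_out)
        if fusion:
            sep_inputs[2] = fuse(d_out[1], d_out[2])  # fusion transmission 2
        s_out = [self.separable[i].forward(sep_inputs[i], train, rng)
                 for i in range(nb)]

        if cfg.use_eca:
            s_out = [self.eca[i].forward(s_out[i], train, rng) for i in range(nb)]

        flat = np.concatenate([s.reshape(b, -1) for s in s_out], axis=1)
        self._sep_shapes = [s.shape for s in s_out]
        h = self.dense1.forward(flat, train, rng)
        h = self.head_act.forward(h, train, rng)
        logits = self.dense2.forward(h, train, rng)
        self.act_taps["penultimate"] = h
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def _rows_to_stack(self, r: np.ndarray) -> np.ndarray:
        """(F, B*C*T) rows -> (B, F, C, T) stack."""
        f = r.shape[0]
        b = self._batch
        cfg = self.config
        return np.ascontiguousarray(
            r.reshape(f, b, cfg.n_electrodes, cfg.n_timesamples)
            .transpose(1, 0, 2, 3))

    def activation_tap(self, name: str) -> np.ndarray:
        """Activations recorded by the last forward call, as (B, F, C, T)."""
        if name == "penultimate":
            return self.act_taps[name]
        return self._rows_to_stack(self._rows_taps[name])

    def gradient_tap(self, name: str) -> np.ndarray:
        """Gradients recorded by the last backward call, as (B, F, C, T)."""
        return self._rows_to_stack(self._grad_rows_taps[name])

    # --------------------------------------------------------------- backward

    def backward(self, dlogits: np.ndarray) -> np.ndarray | None:
        """Backpropagate from the logits of the last forward call.

        Accumulates parameter gradients and records the gradient at each
        temporal stage output (used by Grad-CAM).  Returns the gradient with
        respect to the input batch, or None when input gradients are off.
        """
        cfg = self.config
        nb = len(cfg.branches)
        fusion = cfg.use_fusion and nb == 3
        b = self._batch
        C, T = cfg.n_electrodes, cfg.n_timesamples

        dh = self.dense2.backward(dlogits)
        dh = self.head_act.backward(dh)
        dflat = self.dense1.backward(dh)

        d_s = []
        ofs = 0
        for shape, w in zip(self._sep_shapes, self.branch_widths):
            d_s.append(dflat[:, ofs:ofs + w].reshape(shape))
            ofs += w

        if cfg.use_eca:
            d_s = [self.eca[i].backward(d_s[i]) for i in range(nb)]

        d_sep_in = [self.separable[i].backward(d_s[i]) for i in range(nb)]

        d_d = list(d_sep_in)
        if fusion:
            m1 = self.dw_out[1]
            d_d[1] = d_sep_in[1] + d_sep_in[2][:, :m1]
            d_d[2] = np.ascontiguousarray(d_sep_in[2][:, m1:])

        d_rows = []
        for i in range(nb):
            dtail = self.dw_tail[i].backward(d_d[i])  # (B, M*D, 1, T)
            dy4 = np.ascontiguousarray(
                dtail.reshape(b, self.dw_in[i], cfg.branches[i].depth_mult, T)
                .transpose(1, 0, 2, 3))
            dx4 = self.dw_conv[i]._backward_maps(dy4)  # (M, B, C, T)
            d_rows.append(dx4.reshape(self.dw_in[i], -1))

        d_t = list(d_rows)
        if fusion:
            f1 = cfg.branches[0].f1
            d_t[0] = d_rows[0] + d_rows[1][:f1]
            d_t[1] = np.ascontiguousarray(d_rows[1][f1:])
        for i, g in enumerate(d_t):
            self._grad_rows_taps[f"temporal_{i + 1}"] = g

        dx = None
        for i in range(nb):
            g = d_t[i]
            if self.t_bn[i] is not None:
                g = self.t_bn[i].backward(g)
            gi = self.t_conv[i]._backward_rows(g)
            if gi is not None:
                dx = gi if dx is None else dx + gi
        return dx

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # ------------------------------------------------------------ persistence

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All mutable state (weights + BN running stats) in a stable order."""
        out = {}
        for i, p in enumerate(self.params()):
            out[f"param_{i:03d}"] = p.data
        bn_idx = 0
        for lay in self.layers():
            if isinstance(lay, nn.BatchNorm):
                out[f"bn_{bn_idx:03d}_mean"] = lay.running_mean
                out[f"bn_{bn_idx:03d}_var"] = lay.running_var
                bn_idx += 1
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            src = arrays[f"param_{i:03d}"]
            if src.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at param_{i:03d}: "
                                 f"{src.shape} vs {p.data.shape}")
            p.data = np.ascontiguousarray(src, dtype=DTYPE)
        self_bn = [lay for lay in self.layers() if isinstance(lay, nn.BatchNorm)]
        for j, lay in enumerate(self_bn):
            lay.running_mean = np.ascontiguousarray(
                arrays[f"bn_{j:03d}_mean"], dtype=np.float32)
            lay.running_var = np.ascontiguousarray(
                arrays[f"bn_{j:03d}_var"], dtype=np.float32)


def parameter_count(model: MultiscaleEEGNet) -> int:
    """Exact trainable-parameter total."""
    return int(sum(p.data.size for p in model.params()))


def save_checkpoint(model: MultiscaleEEGNet, path) -> None:
    """Self-describing single-file checkpoint: JSON config + weight arrays."""
    header = json.dumps({"config": model.config.to_dict(), "seed": model.seed})
    arrays = model.state_arrays()
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> MultiscaleEEGNet:
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__header__"}
    model = MultiscaleEEGNet(ModelConfig.from_dict(header["config"]),
                             seed=header.get("seed", 0))
    model.load_state_arrays(arrays)
    return model
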