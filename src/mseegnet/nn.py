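"""Minimal NumPy layer stack with explicit backpropagation.

Every layer implements ``forward(x, train=..., rng=...)`` and ``backward(dy)``;
``backward`` accumulates parameter gradients in :class:`Param` objects and
returns the gradient with respect to its input.  All arithmetic is float32;
convolutions are lowered to im2col windows plus BLAS matmuls, which is what
keeps CPU training of the EEG decoder tractable.

Shape convention for feature stacks (matching the 4-axis contract used by the
model): ``(batch, maps, spatial, time)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "TemporalConv",
    "BatchNorm",
    "DepthwiseSpatialConv",
    "DepthwiseTemporalConv",
    "PointwiseConv",
    "ELU",
    "AvgPoolTime",
    "Dropout",
    "Flatten",
    "Dense",
    "ECAGate",
    "eca_attention",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "glorot_uniform",
]

DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    """Fan-balanced uniform init, U(-limit, limit) with limit = sqrt(6/(fi+fo))."""
    limit = np.sqrt(6.0 / float(fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: stateless unless it owns Params or caches."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool = False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover
        raise NotImplementedError

    def constrain(self) -> None:
        """Apply post-step weight constraints (max-norm); default none."""


def _pad_lr(kernel: int) -> tuple[int, int]:
    # "same" padding split; for even kernels the extra zero goes on the right.
    return (kernel - 1) // 2, kernel // 2


class TemporalConv(Layer):
    """2D conv with F filters of size (1, K), stride 1, same padding, no bias.

    Input (B, 1, C, T) -> output (B, F, C, T).  The electrode axis is carried
    along untouched: each filter is a 1D FIR kernel applied per electrode.
    Lowered to one im2col matrix and BLAS matmuls.  ``input_grad=False`` skips
    the gradient w.r.t. the input in ``backward`` (this is the first layer of
    the network, so that gradient is only needed for input-saliency work).
    """

    def __init__(self, n_filters: int, kernel: int, rng: np.random.Generator):
        self.n_filters = int(n_filters)
        self.kernel = int(kernel)
        if self.kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.w = Param(glorot_uniform(rng, (self.n_filters, self.kernel),
                                      fan_in=self.kernel,
                                      fan_out=self.n_filters * self.kernel))
        self.input_grad = True
        self._cache = None

    def params(self):
        return [self.w]

    def _forward_rows(self, x, col=None):
        """Rows-layout fast path: (B,1,C,T) -> (F, B*C*T)."""
        b, _, c, t = x.shape
        if self.kernel > t:
            raise ValueError(f"kernel {self.kernel} exceeds time length {t}")
        if col is None:
            col = self.im2col(x)
        y = np.matmul(self.w.data, col.T)  # (F, B*C*T), contiguous write
        self._cache = (col, (b, c, t))
        return y

    def im2col(self, x):
        """Sliding-window matrix (B*C*T, K) for the same-padded input."""
        pl, pr = _pad_lr(self.kernel)
        xp = np.pad(x[:, 0], ((0, 0), (0, 0), (pl, pr)))
        col = sliding_window_view(xp, self.kernel, axis=-1).reshape(-1, self.kernel)
        return np.ascontiguousarray(col, dtype=DTYPE)

    def _backward_rows(self, dy_rows):
        """Backward from (F, B*C*T); returns (B,1,C,T) or None (input_grad off)."""
        col, (b, c, t) = self._cache
        k = self.kernel
        pl, _ = _pad_lr(k)
        self.w.grad += dy_rows @ col
        self._cache = None
        if not self.input_grad:
            return None
        dcol = self.w.data.T @ dy_rows  # (K, B*C*T)
        dxp = np.zeros((b * c, t + k - 1), dtype=DTYPE)
        for j in range(k):
            dxp[:, j:j + t] += dcol[j].reshape(b * c, t)
        return dxp.reshape(b, 1, c, t + k - 1)[..., pl:pl + t]

    def forward(self, x, train: bool = False, rng=None):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"TemporalConv expects (B,1,C,T), got {x.shape}")
        b, _, c, t = x.shape
        y = self._forward_rows(x)
        # (F,B,C,T) -> (B,F,C,T): moves whole C*T blocks, memcpy-fast
        return np.ascontiguousarray(
            y.reshape(self.n_filters, b, c, t).transpose(1, 0, 2, 3))

    def backward(self, dy):
        dy2 = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(self.n_filters, -1)
        return self._backward_rows(dy2)


class BatchNorm(Layer):
    """Per-map batch normalization over (batch, spatial, time).

    Accepts the standard 4-axis stack (B, M, S, T) or the rows layout (M, N)
    used on the hot path, where row m holds map m's values for the whole
    batch; statistics are per map in both cases.
    """

    def __init__(self, n_maps: int, eps: float = 1e-5, momentum: float = 0.1):
        self.n_maps = int(n_maps)
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.gamma = Param(np.ones(self.n_maps, dtype=DTYPE))
        self.beta = Param(np.zeros(self.n_maps, dtype=DTYPE))
        self.running_mean = np.zeros(self.n_maps, dtype=DTYPE)
        self.running_var = np.ones(self.n_maps, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _sums(self, x):
        """Per-map (sum, sum-of-squares) pairs, cheap in either layout."""
        if x.ndim == 2:
            s1 = x.sum(axis=1, dtype=np.float64)
            s2 = np.einsum("mn,mn->m", x, x, optimize=True).astype(np.float64)
            n = x.shape[1]
        else:
            b, m, sp, t = x.shape
            x3 = x.reshape(b, m, sp * t)
            s1 = x3.sum(axis=(0, 2), dtype=np.float64)
            s2 = np.einsum("bmn,bmn->m", x3, x3, optimize=True).astype(np.float64)
            n = b * sp * t
        return s1, s2, n

    def _bcast(self, v, ndim):
        return v[:, None] if ndim == 2 else v[None, :, None, None]

    def forward(self, x, train: bool = False, rng=None):
        if train:
            s1, s2, n = self._sums(x)
            mu = s1 / n
            var = np.maximum(s2 / n - mu * mu, 0.0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(np.asarray(var, dtype=np.float64) + self.eps)
        a = (self.gamma.data / std).astype(DTYPE)
        c = (self.beta.data - mu * a).astype(DTYPE)
        self._cache = (x, np.asarray(mu, dtype=np.float64), std, train)
        y = x * self._bcast(a, x.ndim)
        y += self._bcast(c, x.ndim)
        return y

    def backward(self, dy):
        x, mu, std, was_train = self._cache
        if x.ndim == 2:
            sum_dy = dy.sum(axis=1, dtype=np.float64)
            sum_dy_x = np.einsum("mn,mn->m", dy, x, optimize=True).astype(np.float64)
            n = x.shape[1]
        else:
            b, m, sp, t = x.shape
            dy3 = dy.reshape(b, m, sp * t)
            sum_dy = dy3.sum(axis=(0, 2), dtype=np.float64)
            sum_dy_x = np.einsum("bmn,bmn->m", dy3, x.reshape(b, m, sp * t),
                                 optimize=True).astype(np.float64)
            n = b * sp * t
        # sum of dy * xhat, recovered from raw-x reductions
        sum_dy_xhat = (sum_dy_x - mu * sum_dy) / std
        self.gamma.grad += sum_dy_xhat.astype(DTYPE)
        self.beta.grad += sum_dy.astype(DTYPE)
        a = (self.gamma.data / std).astype(DTYPE)
        self._cache = None
        if not was_train:
            return dy * self._bcast(a, dy.ndim)
        # dx = a*(dy - sum_dy/n - xhat*sum_dy_xhat/n), expanded to a*dy + p*x + q
        p = (-a * sum_dy_xhat / (n * std)).astype(DTYPE)
        q = (-a * (sum_dy / n - mu * sum_dy_xhat / (n * std))).astype(DTYPE)
        dx = dy * self._bcast(a, dy.ndim)
        dx += x * self._bcast(p, dy.ndim)
        dx += self._bcast(q, dy.ndim)
        return dx


class DepthwiseSpatialConv(Layer):
    """Depthwise conv with D filters of size (C, 1) per input map.

    Input (B, M, C, T) -> output (B, M*D, 1, T): the electrode axis collapses
    into per-map spatial filters (one learned montage per output map).
    Optional per-filter max-norm constraint (canonical EEGNet uses 1.0).
    """

    def __init__(self, in_maps: int, depth_mult: int, n_electrodes: int,
                 rng: np.random.Generator, max_norm: float | None = 1.0):
        self.in_maps = int(in_maps)
        self.depth_mult = int(depth_mult)
        self.n_electrodes = int(n_electrodes)
        self.max_norm = max_norm
        self.w = Param(glorot_uniform(
            rng, (self.in_maps, self.depth_mult, self.n_electrodes),
            fan_in=self.n_electrodes, fan_out=self.depth_mult * self.n_electrodes))
        self._cache = None

    def params(self):
        return [self.w]

    def _forward_maps(self, x4):
        """Maps-major fast path: (M, B, C, T) -> (M, B, D, T)."""
        m, b, c, t = x4.shape
        if m != self.in_maps or c != self.n_electrodes:
            raise ValueError(
                f"DepthwiseSpatialConv expects {self.in_maps} maps x "
                f"{self.n_electrodes} electrodes, got maps-major {x4.shape}")
        self._cache = x4
        # (M,1,D,C) @ (M,B,C,T) -> (M,B,D,T), batched over maps and batch
        return np.matmul(self.w.data[:, None], x4)

    def _backward_maps(self, dy4):
        x4 = self._cache
        # batched (D,T)@(T,C) with the transpose handled inside BLAS
        dw_bm = np.matmul(dy4, x4.transpose(0, 1, 3, 2))  # (M, B, D, C)
        self.w.grad += dw_bm.sum(axis=1)
        self._cache = None
        return np.matmul(self.w.data.transpose(0, 2, 1)[:, None], dy4)

    def forward(self, x, train: bool = False, rng=None):
        b, m, c, t = x.shape
        y4 = self._forward_maps(np.ascontiguousarray(x.transpose(1, 0, 2, 3)))
        return np.ascontiguousarray(y4.transpose(1, 0, 2, 3)).reshape(
            b, m * self.depth_mult, 1, t)

    def backward(self, dy):
        m, b = self.in_maps, dy.shape[0]
        t = dy.shape[-1]
        dy4 = np.ascontiguousarray(
            dy.reshape(b, m, self.depth_mult, t).transpose(1, 0, 2, 3))
        dx4 = self._backward_maps(dy4)
        return np.ascontiguousarray(dx4.transpose(1, 0, 2, 3))

    def constrain(self):
        if self.max_norm is None:
            return
        norms = np.linalg.norm(self.w.data, axis=2, keepdims=True)
        factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        self.w.data *= factor.astype(DTYPE)


class DepthwiseTemporalConv(Layer):
    """Per-map 1D conv of length K along time, same padding, no bias.

    Input (B, M, 1, T) -> (B, M, 1, T).  First half of a separable conv.
    """

    def __init__(self, n_maps: int, kernel: int, rng: np.random.Generator):
        self.n_maps = int(n_maps)
        self.kernel = int(kernel)
        self.w = Param(glorot_uniform(rng, (self.n_maps, self.kernel),
                                      fan_in=self.kernel, fan_out=self.kernel))
        self._cache = None

    def params(self):
        return [self.w]

    def forward(self, x, train: bool = False, rng=None):
        b, m, s, t = x.shape
        if m != self.n_maps or s != 1:
            raise ValueError(f"DepthwiseTemporalConv expects (B,{self.n_maps},1,T), got {x.shape}")
        if t < 1:
            raise ValueError("empty time axis")
        pl, pr = _pad_lr(self.kernel)
        xp = np.pad(x[:, :, 0], ((0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, self.kernel, axis=-1)  # (B,M,T,K)
        y = np.einsum("bmtk,mk->bmt", win, self.w.data, optimize=True)
        self._cache = (win, (b, m, t))
        return y[:, :, None, :].astype(DTYPE)

    def backward(self, dy):
        win, (b, m, t) = self._cache
        k = self.kernel
        pl, _ = _pad_lr(k)
        dy3 = dy[:, :, 0]
        self.w.grad += np.einsum("bmt,bmtk->mk", dy3, win, optimize=True)
        dxp = np.zeros((b, m, t + k - 1), dtype=DTYPE)
        for j in range(k):
            dxp[:, :, j:j + t] += dy3 * self.w.data[None, :, j:j + 1]
        self._cache = None
        return dxp[:, :, None, pl:pl + t]


class PointwiseConv(Layer):
    """1x1 conv mixing maps: (B, M, S, T) -> (B, F, S, T), no bias."""

    def __init__(self, in_maps: int, out_maps: int, rng: np.random.Generator):
        self.in_maps = int(in_maps)
        self.out_maps = int(out_maps)
        self.w = Param(glorot_uniform(rng, (self.out_maps, self.in_maps),
                                      fan_in=self.in_maps, fan_out=self.out_maps))
        self._cache = None

    def params(self):
        return [self.w]

    def forward(self, x, train: bool = False, rng=None):
        b, m, s, t = x.shape
        if m != self.in_maps:
            raise ValueError(f"PointwiseConv expects {self.in_maps} maps, got {m}")
        y = np.matmul(self.w.data, x.reshape(b, m, s * t))
        self._cache = (x, (b, s, t))
        return y.reshape(b, self.out_maps, s, t)

    def backward(self, dy):
        x, (b, s, t) = self._cache
        dy2 = dy.reshape(b, self.out_maps, s * t)
        x2 = x.reshape(b, self.in_maps, s * t)
        self.w.grad += np.einsum("bft,bmt->fm", dy2, x2, optimize=True)
        dx = np.matmul(self.w.data.T, dy2).reshape(x.shape)
        self._cache = None
        return dx


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train: bool = False, rng=None):
        y = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))).astype(DTYPE)
        self._cache = (x > 0, y)
        return y

    def backward(self, dy):
        pos, y = self._cache
        self._cache = None
        return dy * np.where(pos, np.float32(1.0), y + np.float32(1.0))


class AvgPoolTime(Layer):
    """Non-overlapping average pooling of the stated width along time.

    Output length floor(T / width); a ragged tail is dropped (zero gradient).
    """

    def __init__(self, width: int):
        self.width = int(width)
        if self.width < 1:
            raise ValueError("pool width must be >= 1")
        self._cache = None

    def forward(self, x, train: bool = False, rng=None):
        b, m, s, t = x.shape
        t_out = t // self.width
        if t_out < 1:
            raise ValueError(f"time axis {t} shorter than pool width {self.width}")
        y = x[..., :t_out * self.width].reshape(b, m, s, t_out, self.width).mean(axis=-1)
        self._cache = (t, t_out)
        return y.astype(DTYPE)

    def backward(self, dy):
        t, t_out = self._cache
        b, m, s, _ = dy.shape
        dx = np.zeros((b, m, s, t), dtype=DTYPE)
        dx[..., :t_out * self.width] = np.repeat(dy / self.width, self.width, axis=-1)
        self._cache = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity when eval or p == 0."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = float(p)
        self._mask = None

    def forward(self, x, train: bool = False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in train mode needs an rng")
        keep = np.float32(1.0 - self.p)
        self._mask = (rng.random(x.shape) >= self.p).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        m, self._mask = self._mask, None
        return dy * m


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train: bool = False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Affine map (B, n_in) -> (B, n_out), optional max-norm on weight columns."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 max_norm: float | None = None):
        self.n_in, self.n_out = int(n_in), int(n_out)
        self.max_norm = max_norm
        self.w = Param(glorot_uniform(rng, (self.n_in, self.n_out),
                                      fan_in=self.n_in, fan_out=self.n_out))
        self.b = Param(np.zeros(self.n_out, dtype=DTYPE))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool = False, rng=None):
        self._cache = x
        return x @ self.w.data + self.b.data

    def backward(self, dy):
        x = self._cache
        self.w.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        self._cache = None
        return dy @ self.w.data.T

    def constrain(self):
        if self.max_norm is None:
            return
        norms = np.linalg.norm(self.w.data, axis=0, keepdims=True)
        factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        self.w.data *= factor.astype(DTYPE)


def eca_attention(x: np.ndarray, kernel: np.ndarray, bias: float = 0.0):
    """Efficient channel attention, functional form.

    Given a feature stack ``x`` of shape (B, M, S, T): global-average-pool each
    map to a descriptor z (B, M); slide a length-k 1D kernel over the map axis
    of z with zero "same" padding and add the scalar bias; squash through a
    sigmoid to per-map gates in (0, 1); rescale each map of x by its gate.

    Returns ``(gated, z, gates)``.
    """
    kernel = np.asarray(kernel, dtype=DTYPE).ravel()
    k = kernel.size
    if k < 1 or k % 2 == 0:
        raise ValueError("ECA kernel length must be a positive odd integer")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in ECA input")
    b, m = x.shape[0], x.shape[1]
    z = x.mean(axis=(2, 3))  # (B, M)
    pad = k // 2
    zp = np.pad(z, ((0, 0), (pad, pad)))
    win = sliding_window_view(zp, k, axis=-1)  # (B, M, k)
    pre = win @ kernel + DTYPE(bias)
    gates = 1.0 / (1.0 + np.exp(-pre))
    gated = x * gates[:, :, None, None].astype(DTYPE)
    return gated.astype(DTYPE), z.astype(DTYPE), gates.astype(DTYPE)


class ECAGate(Layer):
    """Efficient channel attention block with a learnable length-k kernel + bias.

    Attends over the *feature-map* axis of a (B, M, 1, T) stack; adds only
    k + 1 parameters.
    """

    def __init__(self, n_maps: int, kernel_size: int, rng: np.random.Generator):
        self.n_maps = int(n_maps)
        self.kernel_size = int(kernel_size)
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("ECA kernel size must be a positive odd integer")
        self.w = Param(glorot_uniform(rng, (self.kernel_size,),
                                      fan_in=self.kernel_size, fan_out=1))
        self.b = Param(np.zeros(1, dtype=DTYPE))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool = False, rng=None):
        gated, z, gates = eca_attention(x, self.w.data, float(self.b.data[0]))
        self._cache = (x, z, gates)
        return gated

    def backward(self, dy):
        x, z, gates = self._cache
        k, pad = self.kernel_size, self.kernel_size // 2
        dx = dy * gates[:, :, None, None]
        dgate = (dy * x).sum(axis=(2, 3))                    # (B, M)
        dpre = (dgate * gates * (1.0 - gates)).astype(DTYPE)  # sigmoid'
        zp = np.pad(z, ((0, 0), (pad, pad)))
        win = sliding_window_view(zp, k, axis=-1)            # (B, M, k)
        self.w.grad += np.einsum("bm,bmk->k", dpre, win, optimize=True)
        self.b.grad += dpre.sum(keepdims=False).reshape(1)
        m = z.shape[1]
        dzp = np.zeros_like(zp)
        for j in range(k):
            dzp[:, j:j + m] += dpre * self.w.data[j]
        dz = dzp[:, pad:pad + m]
        s_t = x.shape[2] * x.shape[3]
        dx = dx + dz[:, :, None, None] / DTYPE(s_t)
        self._cache = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits, probs)."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(DTYPE), probs


class Adam:
    """Adam with the standard bias-corrected moments (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p.data -= (self.lr * (m / b1t)
                       / (np.sqrt(v / b2t) + self.eps)).astype(DTYPE)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
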