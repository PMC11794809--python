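"""Gradient-weighted class-activation attribution over electrodes x time.

Grad-CAM on the temporal-convolution stage: those are the only layers that
still carry the electrode axis, which is what scalp-level interpretation
needs.  The gradient of the target-class *logit* (not the probability —
softmax shift invariance makes the logit the meaningful quantity) is taken
w.r.t. the chosen temporal stage's activations, globally averaged per
feature map to produce map weights, and the weighted activation sum is
rectified (negative evidence clipped) and returned at full (C, T)
resolution.  Nearest-neighbour upsampling covers any pooled axis, though
temporal stages are unpooled.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

from .model import MultiscaleEEGNet
from .synthetic import TrialSet

__all__ = [
    "AttributionMap",
    "gradcam_attribution",
    "export_penultimate_features",
    "input_band_power_map",
]

_TEMPORAL_LAYERS = ("temporal_1", "temporal_2", "temporal_3")


@dataclass
class AttributionMap:
    """Non-negative electrode x time importance for one trial and class."""

    values: np.ndarray      # (n_electrodes, n_timesamples), >= 0
    trial_id: int
    target_class: int
    layer: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("attribution must be (electrodes, time)")
        if np.any(self.values < 0):
            raise ValueError("attribution must be rectified (non-negative)")

    def to_csv(self, path, sidecar: bool = True) -> None:
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            for row in self.values:
                w.writerow([f"{v:.6g}" for v in row])
        if sidecar:
            with open(str(path) + ".json", "w") as f:
                json.dump({"trial_id": self.trial_id,
                           "target_class": self.target_class,
                           "layer": self.layer}, f)

    def per_electrode(self) -> np.ndarray:
        """Mean importance per electrode (for topography-style export)."""
        return self.values.mean(axis=1)


def _nearest_upsample(arr: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a 2-D map to the target shape."""
    c, t = arr.shape
    ci = (np.arange(target[0]) * c) // target[0]
    ti = (np.arange(target[1]) * t) // target[1]
    return arr[np.ix_(ci, ti)]


def gradcam_attribution(model: MultiscaleEEGNet, trial: np.ndarray,
                        target_class: int, layer: str = "temporal_1"
                        ) -> AttributionMap:
    """Grad-CAM map for one trial at one of the temporal stages.

    ``trial`` is (C, T); the model must match its shape.  Raises for layers
    that no longer resolve electrodes (everything after the depthwise
    spatial convolution collapses that axis).
    """
    if layer not in _TEMPORAL_LAYERS:
        raise ValueError(
            f"layer {layer!r} has no electrode-resolved spatial axis; "
            f"use one of {_TEMPORAL_LAYERS} (post-depthwise stages collapse "
            f"the electrode dimension)")
    branch = int(layer.split("_")[1]) - 1
    if branch >= len(model.config.branches):
        raise ValueError(f"model has {len(model.config.branches)} branches; "
                         f"{layer} not available")
    n_classes = model.config.n_classes
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target_class {target_class} out of range")

    trial = np.asarray(trial, dtype=np.float32)
    if trial.ndim != 2:
        raise ValueError("trial must be (C, T)")
    x = trial[None]

    logits = model.forward(x, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    model.backward(dlogits)

    acts = model.activation_tap(layer)[0]    # (F, C, T')
    grads = model.gradient_tap(layer)[0]     # (F, C, T')
    weights = grads.mean(axis=(1, 2))        # global-average map weights
    cam = np.tensordot(weights, acts, axes=(0, 0))   # (C, T')
    cam = np.maximum(cam, 0.0)
    target_shape = (model.config.n_electrodes, model.config.n_timesamples)
    if cam.shape != target_shape:
        cam = _nearest_upsample(cam, target_shape)
    model.zero_grad()
    return AttributionMap(cam, trial_id=-1, target_class=int(target_class),
                          layer=layer)


def input_band_power_map(trial: np.ndarray, fs: float,
                         band: tuple[float, float] = (8.0, 12.0)
                         ) -> np.ndarray:
    """Per-electrode Welch power of the raw trial in ``band``.

    The input-signal counterpart to an attribution map: comparing the two
    shows whether the decoder's highlighted electrodes coincide with where
    the input actually carries band-limited power.  This is an
    interpretation choice — an "input heat map" can be defined several
    ways; spectral power in the physiological band is the one used here.
    """
    import scipy.signal

    trial = np.asarray(trial)
    if trial.ndim != 2:
        raise ValueError("trial must be (C, T)")
    lo, hi = band
    nperseg = min(256, trial.shape[1])
    freqs, psd = scipy.signal.welch(trial, fs=fs, nperseg=nperseg, axis=-1)
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {band} has no Welch bins at this length")
    return psd[:, sel].mean(axis=1)


def export_penultimate_features(model: MultiscaleEEGNet, trials: TrialSet,
                                path=None, batch_size: int = 256,
                                warn_untrained: bool = True):
    """Dense-layer activations (n_trials x dense_units), row-aligned labels.

    These are the embedding-ready features (e.g. for external t-SNE plots).
    Optionally written as CSV with a trailing ``label`` column.
    """
    feats = []
    for s in range(0, trials.n_trials, batch_size):
        model.forward(trials.data[s:s + batch_size], train=False)
        feats.append(model.act_taps["penultimate"].copy())
    feats = (np.concatenate(feats) if feats
             else np.empty((0, model.config.dense_units), dtype=np.float32))
    if path is not None:
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow([f"f{i:02d}" for i in range(feats.shape[1])] + ["label"])
            for row, lab in zip(feats, trials.labels):
                w.writerow([f"{v:.6g}" for v in row] + [int(lab)])
    return feats, trials.labels.copy()
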