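"""Training loop, evaluation protocols, and the ablation grid.

Training follows the decoder's stated recipe: Adam (lr 0.001), batch size
64, cross-entropy loss, a fixed epoch budget with seeded reshuffling each
epoch, and no validation split or early stopping — the final model is
evaluated.  Protocols: within-subject (train/test split by session, one
model per subject) and leave-one-subject-out (one fold per subject).  The
ablation grid trains the four structure combinations (parallel branches
alone, + fusion, + ECA, + both) and reports accuracy/SD/kappa per row plus
exact Wilcoxon p-values against the full model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import nn
from .metrics import accuracy, confusion_matrix, kappa, wilcoxon_signed_rank
from .model import ModelConfig, MultiscaleEEGNet
from .synthetic import TrialSet, split_by_session

__all__ = [
    "TrainConfig",
    "train_model",
    "evaluate_model",
    "MultiscaleEEGNetClassifier",
    "SubjectResult",
    "MetricsReport",
    "within_subject_protocol",
    "loso_protocol",
    "ablation_grid",
    "ABLATION_GRID",
]

logger = logging.getLogger("mseegnet.train")

# im2col caches above this many bytes are rebuilt per batch instead
_COL_CACHE_LIMIT = 2_500_000_000


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults are the decoder's recipe)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 1000
    seed: int = 0
    val_fraction: float = 0.0
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size >= 1 and learning_rate > 0 required")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


def _build_col_cache(model: MultiscaleEEGNet, data: np.ndarray):
    """Per-trial im2col matrices for every temporal branch, or None.

    The matrices depend only on the data, so they are built once per
    training run and gathered per batch.
    """
    n, c, t = data.shape
    total = n * c * t * 4 * sum(conv.kernel for conv in model.t_conv)
    if total > _COL_CACHE_LIMIT:
        return None
    cache = []
    for conv in model.t_conv:
        k = conv.kernel
        pl, pr = (k - 1) // 2, k // 2
        xp = np.pad(data, ((0, 0), (0, 0), (pl, pr)))
        col = sliding_window_view(xp, k, axis=-1).reshape(n, c * t, k)
        cache.append(np.ascontiguousarray(col, dtype=np.float32))
    return cache


def train_model(model: MultiscaleEEGNet, train_set: TrialSet,
                cfg: TrainConfig) -> tuple[MultiscaleEEGNet, list[float]]:
    """Train in place; returns the model and the per-epoch mean loss history."""
    n = train_set.n_trials
    if n == 0:
        raise ValueError("empty training set")
    n_classes = model.config.n_classes
    present = np.unique(train_set.labels)
    if present.size < n_classes:
        warnings.warn(f"training labels cover {present.size} of "
                      f"{n_classes} classes", stacklevel=2)
    data = np.ascontiguousarray(train_set.data, dtype=np.float32)
    labels = train_set.labels
    cols_full = _build_col_cache(model, data)

    model.set_input_grad(False)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed)
    drop_rng = model.make_dropout_rng()

    history: list[float] = []
    for epoch in range(cfg.epochs):
        perm = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, cfg.batch_size):
            idx = perm[s:s + cfg.batch_size]
            cb = (None if cols_full is None else
                  [c[idx].reshape(-1, c.shape[-1]) for c in cols_full])
            logits = model.forward(data[idx], train=True, rng=drop_rng,
                                   cols=cb)
            loss, dlogits, _ = nn.softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch starting {s}; aborting")
            model.backward(dlogits)
            opt.step()
            model.constrain()
            opt.zero_grad()
            epoch_loss += loss * idx.size
        history.append(epoch_loss / n)
        logger.info("epoch %d/%d loss %.4f", epoch + 1, cfg.epochs, history[-1])
    return model, history


def evaluate_model(model: MultiscaleEEGNet, trials: TrialSet,
                   batch_size: int = 256) -> np.ndarray:
    """Predicted labels in eval mode (dropout off, BN running stats)."""
    preds = []
    for s in range(0, trials.n_trials, batch_size):
        preds.append(model.predict(trials.data[s:s + batch_size]))
    return np.concatenate(preds) if preds else np.empty(0, dtype=np.int64)


class MultiscaleEEGNetClassifier:
    """fit/predict wrapper pairing a ModelConfig with a TrainConfig.

    The model config may omit the data shape; it is completed from the
    training trials at fit time.
    """

    def __init__(self, model_config: ModelConfig | dict | None = None,
                 train_config: TrainConfig | None = None, seed: int = 0):
        self.model_config = model_config
        self.train_config = train_config or TrainConfig()
        self.seed = int(seed)
        self.model_: MultiscaleEEGNet | None = None
        self.loss_history_: list[float] = []

    def _resolve_config(self, trials: TrialSet) -> ModelConfig:
        base = self.model_config
        shape = dict(n_electrodes=trials.n_electrodes,
                     n_timesamples=trials.n_timesamples,
                     n_classes=int(trials.labels.max()) + 1)
        if base is None:
            return ModelConfig(**shape)
        if isinstance(base, ModelConfig):
            d = base.to_dict()
        else:
            d = dict(base)
        d.update(shape)
        return ModelConfig.from_dict(d)

    def fit(self, trials: TrialSet) -> "MultiscaleEEGNetClassifier":
        cfg = self._resolve_config(trials)
        self.model_ = MultiscaleEEGNet(cfg, seed=self.seed)
        tc = self.train_config
        tc = TrainConfig(**{**tc.__dict__, "seed": tc.seed + self.seed})
        _, self.loss_history_ = train_model(self.model_, trials, tc)
        return self

    def predict(self, trials: TrialSet | np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("fit before predict")
        if isinstance(trials, TrialSet):
            return evaluate_model(self.model_, trials)
        return self.model_.predict(np.asarray(trials))


@dataclass
class SubjectResult:
    subject: int
    accuracy_pct: float
    kappa: float
    n_test: int
    confusion: np.ndarray


@dataclass
class MetricsReport:
    """Per-subject rows plus the aggregate summary and paired tests."""

    per_subject: list[SubjectResult]
    paired_tests: dict[str, float] = field(default_factory=dict)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy_pct for r in self.per_subject])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.per_subject) > 1 else 0.0

    @property
    def mean_kappa(self) -> float:
        return float(np.mean([r.kappa for r in self.per_subject]))

    def to_csv(self, path) -> None:
        import csv
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["subject", "accuracy_pct", "kappa", "n_test"])
            for r in self.per_subject:
                w.writerow([r.subject, f"{r.accuracy_pct:.4f}",
                            f"{r.kappa:.4f}", r.n_test])

    def aggregate_dict(self) -> dict:
        return {"mean_accuracy_pct": self.mean_accuracy,
                "sd_accuracy_pct": self.sd_accuracy,
                "mean_kappa": self.mean_kappa,
                "n_subjects": len(self.per_subject),
                "paired_tests": dict(self.paired_tests)}

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.aggregate_dict(), f, indent=2)


def _score_subject(subject: int, y_true, y_pred, n_classes: int) -> SubjectResult:
    cm = confusion_matrix(y_true, y_pred, n_classes)
    return SubjectResult(subject=int(subject), accuracy_pct=accuracy(cm),
                         kappa=kappa(cm), n_test=int(cm.sum()), confusion=cm)


def within_subject_protocol(trials: TrialSet, model_factory,
                            train_sessions=(0,), test_sessions=(1,)
                            ) -> MetricsReport:
    """Per subject: fit on the designated sessions, test on the held-out ones.

    ``model_factory(seed)`` must return an object with ``fit(TrialSet)`` and
    ``predict(TrialSet)``.
    """
    n_classes = int(trials.labels.max()) + 1
    rows = []
    for subj in np.unique(trials.subject_id):
        sub = trials.select(trials.subject_id == subj)
        if np.unique(sub.session_id).size < 2:
            raise ValueError(f"subject {subj} has a single session; "
                             f"cannot hold one out")
        tr, te = split_by_session(sub, list(train_sessions), list(test_sessions))
        est = model_factory(int(subj))
        est.fit(tr)
        rows.append(_score_subject(subj, te.labels, est.predict(te), n_classes))
    return MetricsReport(per_subject=rows)


def loso_protocol(trials: TrialSet, model_factory) -> MetricsReport:
    """Leave-one-subject-out: one fold per subject, no subject leakage."""
    subjects = np.unique(trials.subject_id)
    if subjects.size < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    n_classes = int(trials.labels.max()) + 1
    rows = []
    for subj in subjects:
        train = trials.select(trials.subject_id != subj)
        test = trials.select(trials.subject_id == subj)
        est = model_factory(int(subj))
        est.fit(train)
        rows.append(_score_subject(subj, test.labels, est.predict(test), n_classes))
    return MetricsReport(per_subject=rows)


# Table rows of the structure study: (fusion transmission, ECA block)
ABLATION_GRID = [
    {"parallel": True, "fusion": False, "eca": False},
    {"parallel": True, "fusion": True, "eca": False},
    {"parallel": True, "fusion": False, "eca": True},
    {"parallel": True, "fusion": True, "eca": True},
]


def ablation_grid(trials: TrialSet, train_config: TrainConfig | None = None,
                  model_config: ModelConfig | dict | None = None,
                  train_sessions=(0,), test_sessions=(1,)) -> list[dict]:
    """Run the four structure combinations; Wilcoxon p-values vs the full model.

    Returns one dict per row with the switch pattern, accuracy mean/SD,
    kappa, per-subject accuracies, and (for rows 1-3) the exact two-sided
    signed-rank p-value against row 4 when enough subjects are available.
    """
    base = {} if model_config is None else (
        model_config.to_dict() if isinstance(model_config, ModelConfig)
        else dict(model_config))
    base.pop("use_fusion", None)
    base.pop("use_eca", None)
    rows = []
    for spec_row in ABLATION_GRID:
        mc = dict(base, use_fusion=spec_row["fusion"], use_eca=spec_row["eca"])
        factory = lambda seed, mc=mc: MultiscaleEEGNetClassifier(
            model_config=mc, train_config=train_config, seed=seed)
        report = within_subject_protocol(trials, factory,
                                         train_sessions, test_sessions)
        rows.append({**spec_row,
                     "accuracy_pct": report.mean_accuracy,
                     "sd_pct": report.sd_accuracy,
                     "kappa": report.mean_kappa,
                     "per_subject": report.accuracies.tolist()})
    full = np.array(rows[-1]["per_subject"])
    for row in rows[:-1]:
        other = np.array(row["per_subject"])
        if full.size >= 5 and np.any(full != other):
            row["p_vs_full"] = wilcoxon_signed_rank(full, other)
        else:
            row["p_vs_full"] = None
    rows[-1]["p_vs_full"] = None
    return rows
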