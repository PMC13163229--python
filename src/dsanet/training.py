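"""Two-stage transfer-learning protocol and cross-validation.

Stage 1 (epochs 1–25 by default) trains the streams, attention/fusion blocks
and head with the backbone frozen, Adam at lr 0.001 and binary cross-entropy;
validation AUC is monitored with early-stopping patience 7 and the learning
rate is halved after 3 consecutive non-improving epochs. Stage 2 (epochs
26–50) unfreezes the backbone at lr 0.0001 (one tenth of stage 1) with
patiences 10 and 7. Best-AUC weights are restored at the end of each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tensor as T
from .data_io import SliceRecord, preprocess
from .evaluation import roc_curve_auc
from .network import DualStreamModel, ModelConfig, build_model, predict
from .tensor import Tensor

__all__ = [
    "calibrate_batchnorm",
    "StageConfig",
    "TrainingHistory",
    "Adam",
    "train_two_stage",
    "cross_validate",
    "fold_summary",
    "records_to_arrays",
]


@dataclass
class StageConfig:
    epoch_range: tuple[int, int]
    backbone_frozen: bool
    learning_rate: float
    early_stop_patience: int
    lr_reduce_factor: float = 0.5
    lr_reduce_patience: int = 3
    monitor: str = "val_auc"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience < 1 or self.lr_reduce_patience < 1:
            raise ValueError("patiences must be >= 1")
        if not 0.0 < self.lr_reduce_factor < 1.0:
            raise ValueError("lr_reduce_factor must be in (0,1)")

    @classmethod
    def stage1(cls, **overrides) -> "StageConfig":
        kw = dict(epoch_range=(1, 25), backbone_frozen=True, learning_rate=1e-3, early_stop_patience=7, lr_reduce_patience=3)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def stage2(cls, **overrides) -> "StageConfig":
        kw = dict(epoch_range=(26, 50), backbone_frozen=False, learning_rate=1e-4, early_stop_patience=10, lr_reduce_patience=7)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrainingHistory:
    rows: list[dict] = field(default_factory=list)
    stage_boundary: int | None = None
    stopping: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def lr_trace(self, stage: int | None = None) -> list[float]:
        return [r["lr"] for r in self.rows if stage is None or r["stage"] == stage]

    def metric(self, name: str) -> list[float]:
        return [r[name] for r in self.rows]


class Adam:
    """Adam optimizer (betas 0.9/0.999, epsilon 1e-7); ``lr`` is mutable so
    plateau scheduling can rescale it between epochs."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, epsilon: float = 1e-7):
        self.lr = lr
        self.beta1, self.beta2, self.epsilon = beta1, beta2, epsilon
        self.state: dict[int, tuple] = {}
        self.t = 0

    def step(self, params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in params:
            g = p.tensor.grad
            if g is None:
                continue
            m, v = self.state.get(id(p), (np.zeros_like(p.data), np.zeros_like(p.data)))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.state[id(p)] = (m, v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.epsilon)


def calibrate_batchnorm(model, x: np.ndarray, batch_size: int = 32, passes: int = 2, momentum: float = 0.5) -> None:
    """Set batch-norm moving statistics from forward passes over ``x``.

    A randomly initialized backbone starts with moving mean 0 / variance 1,
    which mismatches real activation statistics; frozen-stage training then
    sees arbitrarily scaled features. (A pretrained backbone ships with
    calibrated statistics, so this step is a no-op in spirit there.) Only the
    moving statistics change — no learnable weight is touched — and the
    procedure is deterministic, so it belongs before stage 1 rather than
    inside it.
    """
    from .layers import BatchNorm

    bns = [layer for layer in model.walk() if isinstance(layer, BatchNorm)]
    saved = [(bn.momentum, bn.trainable) for bn in bns]
    for bn in bns:
        bn.momentum = momentum
        bn.trainable = True
    try:
        for _ in range(passes):
            for lo in range(0, len(x), batch_size):
                model.forward(Tensor(x[lo : lo + batch_size]), training=True)
    finally:
        for bn, (mom, tr) in zip(bns, saved):
            bn.momentum = mom
            bn.trainable = tr


def _bce_loss(p: Tensor, y: np.ndarray) -> Tensor:
    eps = Tensor(1e-7)
    yt = Tensor(y.reshape(-1, 1))
    one = Tensor(1.0)
    return -T.reduce_mean(yt * T.log(p + eps) + (one - yt) * T.log(one - p + eps))


def records_to_arrays(records: list[SliceRecord], size: int):
    """Preprocess records into a network-ready (N, size, size, 3) batch."""
    x = np.stack([preprocess(r, size=size) for r in records])
    y = np.array([r.label for r in records], dtype=float)
    return x, y


def _as_arrays(dataset, size):
    if isinstance(dataset, tuple):
        return np.asarray(dataset[0], dtype=float), np.asarray(dataset[1], dtype=float)
    return records_to_arrays(dataset, size)


def _evaluate(model, x, y, batch_size):
    p = predict(model, x, batch_size=batch_size)
    eps = 1e-7
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    acc = float(np.mean((p >= 0.5) == y))
    _, auc = roc_curve_auc(y, p)
    return loss, acc, auc, p


def _run_stage(model, stage, opt, xtr, ytr, xval, yval, batch_size, rng, history, stage_no):
    es_wait = lr_wait = 0
    best = -np.inf
    best_weights = None
    first, last = stage.epoch_range
    reason = "completed"
    for epoch in range(first, last + 1):
        order = rng.permutation(len(xtr))
        losses, preds = [], np.empty(len(xtr))
        for lo in range(0, len(xtr), batch_size):
            idx = order[lo : lo + batch_size]
            xb = Tensor(xtr[idx])
            p = model.forward(xb, training=True)
            loss = _bce_loss(p, ytr[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch} (lr={opt.lr:.2e}); aborting")
            for prm in model.params():
                prm.tensor.zero_grad()
            loss.backward()
            opt.step(model.trainable_params())
            losses.append(float(loss.data) * len(idx))
            preds[idx] = p.data[:, 0]
        train_loss = float(np.sum(losses) / len(xtr))
        train_acc = float(np.mean((preds >= 0.5) == ytr))
        _, train_auc = roc_curve_auc(ytr, preds)
        val_loss, val_acc, val_auc, _ = _evaluate(model, xval, yval, batch_size)
        history.rows.append(
            {
                "epoch": epoch,
                "stage": stage_no,
                "lr": opt.lr,
                "train_loss": train_loss,
                "train_acc": train_acc,
                "train_auc": train_auc,
                "val_loss": val_loss,
                "val_acc": val_acc,
                "val_auc": val_auc,
            }
        )
        monitored = {"val_auc": val_auc, "val_loss": -val_loss, "val_acc": val_acc}[stage.monitor]
        if monitored > best:
            best = monitored
            best_weights = model.get_weights()
            es_wait = lr_wait = 0
        else:
            es_wait += 1
            lr_wait += 1
            if lr_wait >= stage.lr_reduce_patience:
                opt.lr *= stage.lr_reduce_factor
                lr_wait = 0
            if es_wait >= stage.early_stop_patience:
                reason = "early_stop"
                break
    if best_weights is not None:  # restore best-AUC weights at stage end
        model.set_weights(best_weights)
    history.stopping[f"stage{stage_no}"] = {"epoch": history.rows[-1]["epoch"], "reason": reason, "best": best}


def train_two_stage(
    model: DualStreamModel,
    train_set,
    val_set,
    stage1: StageConfig | None = None,
    stage2: StageConfig | None = None,
    batch_size: int = 64,
    seed: int = 0,
):
    """Run the freeze → fine-tune protocol; returns (model, TrainingHistory).

    ``train_set``/``val_set`` are either ``(X, y)`` arrays or lists of
    SliceRecords (preprocessed to the model's input size). Deterministic for
    a fixed (model seed, trainer seed) pair.
    """
    stage1 = stage1 or StageConfig.stage1()
    stage2 = stage2 or StageConfig.stage2()
    size = model.config.input_size
    xtr, ytr = _as_arrays(train_set, size)
    xval, yval = _as_arrays(val_set, size)
    if len(np.unique(yval)) < 2:
        raise ValueError("validation set must contain both classes (AUC is monitored)")
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    history = TrainingHistory()

    model.backbone.set_trainable(not stage1.backbone_frozen)
    opt1 = Adam(lr=stage1.learning_rate)
    _run_stage(model, stage1, opt1, xtr, ytr, xval, yval, batch_size, rng, history, stage_no=1)
    history.stage_boundary = history.rows[-1]["epoch"]

    model.backbone.set_trainable(not stage2.backbone_frozen)
    opt2 = Adam(lr=stage2.learning_rate)
    _run_stage(model, stage2, opt2, xtr, ytr, xval, yval, batch_size, rng, history, stage_no=2)
    return model, history


# -- cross-validation ------------------------------------------------------


def fold_summary(values) -> dict:
    """Mean and sample standard deviation (ddof=1) across folds."""
    values = np.asarray(values, dtype=float)
    return {"mean": float(values.mean()), "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0}


def default_fold_runner(model_config: ModelConfig, stage1=None, stage2=None, batch_size=16):
    """Build a fold runner that trains a fresh model per fold and reports
    accuracy, macro F1 and AUC on the fold's validation split."""

    def run(train_records, val_records, fold_seed):
        from .evaluation import classification_metrics, confusion_matrix

        model = build_model(model_config, seed=fold_seed)
        size = model_config.input_size
        xtr, ytr = records_to_arrays(train_records, size)
        xval, yval = records_to_arrays(val_records, size)
        train_two_stage(model, (xtr, ytr), (xval, yval), stage1, stage2, batch_size=batch_size, seed=fold_seed)
        p = predict(model, xval, batch_size=batch_size)
        cm = confusion_matrix(yval.astype(int), (p >= 0.5).astype(int))
        rep = classification_metrics(cm)
        _, auc = roc_curve_auc(yval, p)
        f1s = [rep.per_class[c]["f1"] for c in (0, 1)]
        macro_f1 = float(np.mean([v for v in f1s if v is not None])) if any(v is not None for v in f1s) else 0.0
        return {"accuracy": rep.accuracy, "macro_f1": macro_f1, "auc": auc}

    return run


def cross_validate(
    records: list[SliceRecord],
    k: int = 5,
    seed: int = 0,
    train_eval_fn=None,
    group_by_patient: bool = False,
    model_config: ModelConfig | None = None,
    stage1: StageConfig | None = None,
    stage2: StageConfig | None = None,
    batch_size: int = 16,
):
    """Stratified k-fold cross-validation.

    Each record lands in exactly one validation fold; folds are stratified by
    label and optionally grouped by patient. Returns per-fold metric dicts
    plus mean ± sample sd for accuracy, macro F1 and AUC.
    """
    from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.array([r.label for r in records])
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"k={k} exceeds the smaller class count ({counts.min()})")
    if train_eval_fn is None:
        train_eval_fn = default_fold_runner(model_config or ModelConfig.smoke(), stage1, stage2, batch_size)
    idx = np.arange(len(records))
    if group_by_patient:
        groups = np.array([r.patient_id for r in records])
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx, labels, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx, labels)
    per_fold = []
    fold_indices = []
    for fold, (tr, va) in enumerate(splits):
        if len(np.unique(labels[va])) < 2:
            raise ValueError(f"fold {fold} is missing a class")
        metrics = train_eval_fn([records[i] for i in tr], [records[i] for i in va], fold_seed=seed + fold)
        per_fold.append(metrics)
        fold_indices.append(va)
    summary = {name: fold_summary([m[name] for m in per_fold]) for name in per_fold[0]}
    return {"per_fold": per_fold, "summary": summary, "fold_indices": fold_indices}
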