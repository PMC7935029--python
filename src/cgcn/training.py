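"""Clip preparation and the cGCN training protocol.

Records are cut into fixed-length non-overlapping clips (100 frames by
default), each clip inheriting its record's label.  Optimization is Adam on
cross-entropy plus an L2 penalty, with a stepwise learning-rate decay when
validation accuracy stops improving (floored at 1e-6), and parameters
snapshotted only when a new best validation accuracy is reached.  The L2
coefficient is chosen by a sweep over a fixed grid, keeping the run with
the best validation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fc_graph import RoiTimeSeries
from .nn import CgcnModel

__all__ = ["Clip", "TrainConfig", "TrainResult", "make_clips", "train_model", "l2_sweep"]


@dataclass
class Clip:
    """One training sample: a fixed-length window of a record."""

    data: np.ndarray  # (clip_length, N)
    label: object
    subject_id: str
    session_id: str
    site_label: str


@dataclass
class TrainConfig:
    clip_length: int = 100
    batch_size: int = 8
    max_epochs: int = 30
    initial_lr: float = 0.01
    lr_decay_factor: float = 0.5
    lr_patience_epochs: int = 5
    min_lr: float = 1e-6
    l2_grid: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip_length < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("clip_length, batch_size and max_epochs must be positive")
        if not (0.0 < self.lr_decay_factor < 1.0):
            raise ValueError("lr_decay_factor must lie in (0, 1)")
        if self.min_lr > self.initial_lr:
            raise ValueError("min_lr must not exceed initial_lr")
        if len(self.l2_grid) == 0:
            raise ValueError("l2_grid must be non-empty")
        if any(l2 < 0 for l2 in self.l2_grid):
            raise ValueError("l2 values must be non-negative")


@dataclass
class TrainResult:
    best_model: CgcnModel
    best_val_accuracy: float
    history: list[dict] = field(default_factory=list)
    chosen_l2: float = 0.0
    classes: list = field(default_factory=list)


def make_clips(record: RoiTimeSeries, clip_length: int) -> list[Clip]:
    """Cut a record into non-overlapping ``clip_length``-frame windows.

    Windows are consecutive and in temporal order; a trailing remainder
    shorter than ``clip_length`` is dropped.
    """
    if clip_length < 1:
        raise ValueError("clip_length must be positive")
    t = record.n_frames
    if t < clip_length:
        raise ValueError(
            f"record {record.subject_id}/{record.session_id} has {t} frames, "
            f"fewer than clip_length={clip_length}"
        )
    clips = []
    for start in range(0, t - clip_length + 1, clip_length):
        clips.append(
            Clip(
                data=record.signals[start:start + clip_length].copy(),
                label=record.class_label,
                subject_id=record.subject_id,
                session_id=record.session_id,
                site_label=record.site_label,
            )
        )
    return clips


def _one_hot(labels: np.ndarray, classes: list) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    y = np.zeros((len(labels), len(classes)))
    for row, lab in enumerate(labels):
        y[row, index[lab]] = 1.0
    return y


def _l2_penalty(model: CgcnModel) -> float:
    return sum(float(np.sum(v ** 2)) for k, v in model.params.items() if k.endswith(".W")
               or k.endswith("Wx") or k.endswith("Wh"))


def _accuracy(model: CgcnModel, clips: list[Clip], classes: list) -> float:
    probs = model.predict_proba([c.data for c in clips])
    pred = probs.argmax(axis=1)
    index = {c: i for i, c in enumerate(classes)}
    truth = np.array([index[c.label] for c in clips])
    return float(np.mean(pred == truth))


class _Adam:
    """Adam over a flat parameter dict (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, np.ndarray]):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)


def train_model(model: CgcnModel, train_clips: list[Clip], val_clips: list[Clip],
                cfg: TrainConfig) -> TrainResult:
    """Adam training with stepwise LR decay and best-validation checkpointing.

    The loss is categorical cross-entropy plus ``l2_lambda`` (taken from the
    model config) times the sum of squared weight-matrix entries.  After
    each epoch the model is scored on ``val_clips``; the learning rate is
    multiplied by ``lr_decay_factor`` when validation accuracy has not
    improved for ``lr_patience_epochs`` epochs (never below ``min_lr``), and
    parameters are snapshotted only on a new best validation accuracy.
    """
    if not train_clips or not val_clips:
        raise ValueError("train and validation clip sets must be non-empty")
    classes = sorted({c.label for c in train_clips}, key=repr)
    val_labels = {c.label for c in val_clips}
    if not val_labels <= set(classes):
        raise ValueError("validation labels must be a subset of training labels")
    if len(classes) != model.config.n_classes:
        raise ValueError(
            f"model expects {model.config.n_classes} classes, "
            f"training data has {len(classes)}"
        )

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params)
    l2 = model.config.l2_lambda
    lr = cfg.initial_lr

    best_val = -1.0
    best_params = None
    epochs_since_best = 0
    history: list[dict] = []

    x_all = np.stack([c.data for c in train_clips])
    y_all = _one_hot(np.array([c.label for c in train_clips], dtype=object), classes)
    n_train = len(train_clips)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_train)
        losses, hits = [], 0
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            probs, cache = model.forward_batch(xb, need_cache=True, train=True)
            ce = -np.mean(np.log(np.sum(probs * yb, axis=1) + 1e-12))
            loss = ce + l2 * _l2_penalty(model)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: ce={ce}, lr={lr}"
                )
            losses.append(loss)
            hits += int(np.sum(probs.argmax(1) == yb.argmax(1)))
            d_logits = (probs - yb) / len(idx)
            grads = model.backward_batch(cache, d_logits)
            if l2 > 0:
                for k in grads:
                    if k.endswith(".W") or k.endswith("Wx") or k.endswith("Wh"):
                        grads[k] += 2.0 * l2 * model.params[k]
            opt.step(model.params, grads, lr)

        val_acc = _accuracy(model, val_clips, classes)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": hits / n_train,
            "val_acc": val_acc,
            "lr": lr,
        })
        if val_acc > best_val:
            best_val = val_acc
            best_params = ({k: v.copy() for k, v in model.params.items()},
                           {k: v.copy() for k, v in model.buffers.items()})
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.lr_patience_epochs:
                lr = max(lr * cfg.lr_decay_factor, cfg.min_lr)
                epochs_since_best = 0

    best_model = CgcnModel(model.config, model.graph, best_params[0], best_params[1])
    return TrainResult(best_model=best_model, best_val_accuracy=best_val,
                       history=history, chosen_l2=l2, classes=classes)


def l2_sweep(model_factory, train_clips: list[Clip], val_clips: list[Clip],
             cfg: TrainConfig) -> TrainResult:
    """Train once per L2 value and keep the best-validation run.

    ``model_factory(l2_lambda, seed)`` must return a freshly initialized
    model; the seed is offset by the grid index so runs are independent.
    Ties are broken toward the smaller L2 value.
    """
    best: TrainResult | None = None
    for i, l2 in enumerate(cfg.l2_grid):
        model = model_factory(l2, cfg.seed + i)
        result = train_model(model, train_clips, val_clips, cfg)
        result.chosen_l2 = l2
        if best is None or result.best_val_accuracy > best.best_val_accuracy or (
            result.best_val_accuracy == best.best_val_accuracy and l2 < best.chosen_l2
        ):
            best = result
    return best
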