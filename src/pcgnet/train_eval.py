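"""Training (Adam + cross-entropy) and evaluation of the 1D-CNN.

The positive class is **abnormal** throughout: recall is sensitivity to
disease, specificity is the true-negative rate on normal recordings.
ROC/AUC are threshold-free; hard labels use a 0.5 cut on P(abnormal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .cnn_model import CNN1D, ModelConfig, TrainedModel, build_model, sigmoid, softmax
from .errors import TrainingError, ValidationError
from .segment_augment import LabeledDataset

EPS = 1e-7  # probability clip in the loss


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Adam defaults are the conventional (beta1, beta2, eps) =
    (0.9, 0.999, 1e-8) with learning rate 1e-3.
    """

    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    early_stop_patience: Optional[int] = None
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValidationError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if self.epochs < 1:
            raise ValidationError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValidationError(f"batch_size must be >= 1, got {self.batch_size}")


@dataclass
class ConfusionMatrix:
    """Binary confusion counts; positive class = abnormal."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    """Headline classification metrics; a ratio with a zero denominator is
    reported as None with the reason in ``undefined``."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    specificity: Optional[float]
    undefined: dict = field(default_factory=dict)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# loss


def _as_binary_labels(true_labels) -> np.ndarray:
    y = np.asarray(true_labels)
    if y.ndim == 2:  # one-hot [normal, abnormal]
        y = y[:, -1]
    y = y.astype(np.float64)
    if not np.all((y == 0) | (y == 1)):
        raise ValidationError("labels must be binary (0/1 or one-hot)")
    return y


def _as_abnormal_prob(predicted) -> np.ndarray:
    p = np.asarray(predicted, dtype=np.float64)
    if p.ndim == 2:
        p = p[:, -1]
    return p


def cross_entropy(true_labels, predicted) -> float:
    """Mean binary cross-entropy, probabilities clipped to [eps, 1-eps].

    Accepts labels as 0/1 or one-hot rows, and predictions as P(abnormal)
    or two-column probability rows.
    """
    y = _as_binary_labels(true_labels)
    p = _as_abnormal_prob(predicted)
    if y.shape != p.shape:
        raise ValidationError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# optimiser


class _Adam:
    def __init__(self, net: CNN1D, cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        self.m = {}
        self.v = {}
        for i, name, arr in net.parameters():
            key = (i, name)
            self.m[key] = np.zeros_like(arr, dtype=np.float32)
            self.v[key] = np.zeros_like(arr, dtype=np.float32)

    def step(self, net: CNN1D) -> None:
        c = self.cfg
        self.t += 1
        bias1 = 1.0 - c.beta1**self.t
        bias2 = 1.0 - c.beta2**self.t
        for i, layer in enumerate(net.layers):
            for name, arr in layer.params.items():
                g = layer.grads[name].astype(np.float32)
                key = (i, name)
                self.m[key] = c.beta1 * self.m[key] + (1 - c.beta1) * g
                self.v[key] = c.beta2 * self.v[key] + (1 - c.beta2) * g * g
                mhat = self.m[key] / bias1
                vhat = self.v[key] / bias2
                arr -= c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)


# ---------------------------------------------------------------------------
# training


def _loss_and_dlogits(net: CNN1D, logits: np.ndarray, y: np.ndarray):
    n = y.shape[0]
    if net.config.head == "softmax2":
        probs = softmax(logits)
        p_correct = np.clip(probs[np.arange(n), y.astype(int)], EPS, 1.0)
        loss = float(-np.mean(np.log(p_correct)))
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y.astype(int)] = 1.0
        dlogits = (probs - onehot) / n
        p_abn = probs[:, 1]
    else:
        p = sigmoid(logits)[:, 0]
        pc = np.clip(p, EPS, 1.0 - EPS)
        loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
        dlogits = ((p - y) / n)[:, None]
        p_abn = p
    return loss, dlogits.astype(np.float32), p_abn


def _epoch_eval(net: CNN1D, X: np.ndarray, y: np.ndarray, batch_size: int):
    probs = net.predict_proba(X, batch_size=batch_size)
    p_abn = _as_abnormal_prob(probs)
    loss = cross_entropy(y, p_abn)
    acc = float(np.mean((p_abn >= 0.5).astype(int) == y))
    return loss, acc


def train(
    model: TrainedModel,
    train_set: LabeledDataset,
    val_set: LabeledDataset,
    config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Mini-batch Adam on the cross-entropy loss.

    Per-epoch train/val loss and accuracy are appended to
    ``model.training_history``.  With early stopping enabled the returned
    weights are those of the best-validation-loss epoch; otherwise the
    final epoch.  Fully reproducible from (config.seed, data order).
    """
    config.validate()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValidationError("train and validation sets must be nonempty")
    Xtr, ytr = train_set.to_arrays()
    Xva, yva = val_set.to_arrays()
    want = model.config.input_len
    if Xtr.shape[1] != want or Xva.shape[1] != want:
        raise ValidationError(
            f"segment length mismatch: model expects {want}, "
            f"got train={Xtr.shape[1]} val={Xva.shape[1]}"
        )

    net = model.net
    opt = _Adam(net, config)
    rng = np.random.default_rng(config.seed)
    best_val = np.inf
    best_state = None
    since_best = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(ytr))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits = net.forward_logits(xb, train=True)
            loss, dlogits, p_abn = _loss_and_dlogits(net, logits, yb)
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged to non-finite value at epoch {epoch}")
            net.backward(dlogits)
            opt.step(net)
            losses.append(loss * len(idx))
            hits += int(np.sum((p_abn >= 0.5).astype(int) == yb))
            seen += len(idx)
        train_loss = float(np.sum(losses) / seen)
        train_acc = hits / seen
        val_loss, val_acc = _epoch_eval(net, Xva, yva, config.batch_size)
        model.training_history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_acc": train_acc,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if config.early_stop_patience is not None:
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = {k: v.copy() for k, v in net.state_arrays().items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.early_stop_patience:
                    break

    if config.early_stop_patience is not None and best_state is not None:
        net.load_state_arrays(best_state)
    return model


# ---------------------------------------------------------------------------
# evaluation


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Exact confusion counts with abnormal (1) as the positive class."""
    y = _as_binary_labels(true_labels)
    yhat = _as_binary_labels(predicted_labels)
    if y.shape != yhat.shape:
        raise ValidationError(f"length mismatch: {y.shape} vs {yhat.shape}")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, precision, recall (sensitivity), F1, specificity.

    A metric whose denominator is zero is returned as None and explained
    in ``Metrics.undefined`` rather than silently reported as 0.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    undefined = {}

    accuracy = (cm.tp + cm.tn) / cm.total

    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision = None
        undefined["precision"] = "no predicted positives (tp + fp = 0)"
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall = None
        undefined["recall"] = "no actual positives (tp + fn = 0)"
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
        undefined["f1"] = "precision or recall undefined or both zero"
    if cm.tn + cm.fp > 0:
        specificity = cm.tn / (cm.tn + cm.fp)
    else:
        specificity = None
        undefined["specificity"] = "no actual negatives (tn + fp = 0)"

    return Metrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        undefined=undefined,
    )


def roc_auc(true_labels, scores) -> ROCCurve:
    """ROC curve over every distinct score threshold, AUC by trapezoid.

    Equal scores are grouped into a single threshold step, which makes
    the trapezoidal area equal to the Mann–Whitney statistic
    (wins + half-ties over all positive–negative pairs).
    """
    y = _as_binary_labels(true_labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValidationError(f"length mismatch: {y.shape} labels vs {s.shape} scores")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"ROC needs both classes, got {n_pos} positives and {n_neg} negatives"
        )

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # indices where the score changes: close a tie group there
    distinct = np.where(np.diff(s_sorted))[0]
    boundaries = np.concatenate([distinct, [len(s_sorted) - 1]])
    tps = np.cumsum(y_sorted)[boundaries]
    fps = np.cumsum(1 - y_sorted)[boundaries]

    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[boundaries]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def evaluate(model: TrainedModel, dataset: LabeledDataset, threshold: float = 0.5) -> dict:
    """Full evaluation report: confusion cells, metrics, AUC, ROC points."""
    if len(dataset) == 0:
        raise ValidationError("cannot evaluate on an empty dataset")
    X, y = dataset.to_arrays()
    if X.shape[1] != model.config.input_len:
        raise ValidationError(
            f"segment length mismatch: model expects {model.config.input_len}, "
            f"got {X.shape[1]}"
        )
    probs = model.net.predict_proba(X)
    p_abn = _as_abnormal_prob(probs)
    cm = confusion(y, (p_abn >= threshold).astype(int))
    metrics = compute_metrics(cm)
    roc = roc_auc(y, p_abn)
    return {
        "n": int(len(dataset)),
        "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        "metrics": {
            "accuracy": metrics.accuracy,
            "precision": metrics.precision,
            "recall": metrics.recall,
            "f1": metrics.f1,
            "specificity": metrics.specificity,
        },
        "metrics_undefined": metrics.undefined,
        "auc": roc.auc,
        "roc": {
            "fpr": roc.fpr.tolist(),
            "tpr": roc.tpr.tolist(),
            "thresholds": [float(t) for t in roc.thresholds],
        },
    }


def history_to_csv(model: TrainedModel, path) -> None:
    """Training history as CSV (epoch, train_loss, train_acc, val_loss, val_acc)."""
    import pandas as pd

    pd.DataFrame(model.training_history).to_csv(path, index=False)


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
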