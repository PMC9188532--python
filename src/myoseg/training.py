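"""Optimization loop, regularization, LR scheduling and hyperband search.

Training uses mini-batch stochastic optimization with the AMSGrad variant of
Adam (batch size 5 by default), an L2 weight penalty, dropout on the input
layer, and a schedule that halves the learning rate when the validation loss
shows no improvement for 4 epochs.  Hyperparameters (lr, dr, reg) are tuned
with the hyperband algorithm (successive halving with eta = 3) scoring
configurations by their validation metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .losses_metrics import EPS, categorical_accuracy, mean_dice
from .nn import AMSGrad, ReduceLROnPlateau
from .nn.core import softmax

__all__ = ["TrainConfig", "train", "hyperband_search"]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    lr = learning rate, dropout_rate = input-layer dropout, l2_factor =
    weight-decay coefficient; the plateau schedule halves lr after
    ``plateau_patience`` epochs without validation-loss improvement.
    """

    lr: float = 0.009765
    dropout_rate: float = 0.2
    l2_factor: float = 0.01
    batch_size: int = 5
    epochs: int = 40
    plateau_factor: float = 0.5
    plateau_patience: int = 4
    seed: int = 0


def _as_batch_images(images) -> np.ndarray:
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[:, None, :, :]
    return x


def _segmentation_loss_and_grad(logits, labels, weight_maps):
    """Weighted cross-entropy (pixel sum per image, batch mean) and d/dlogits."""
    n, k = logits.shape[0], logits.shape[1]
    p = softmax(logits, axis=1)
    onehot = np.eye(k)[labels].transpose(0, 3, 1, 2)
    p_true = np.clip(np.take_along_axis(p, labels[:, None], axis=1)[:, 0], EPS, None)
    loss = float(-np.sum(weight_maps * np.log(p_true)) / n)
    grad = weight_maps[:, None] * (p - onehot) / n
    return loss, grad


def _classification_loss_and_grad(logits, onehot):
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    loss = float(-np.sum(onehot * np.log(np.clip(p, EPS, None))) / n)
    return loss, (p - onehot) / n


def _eval_segmenter(model, x, labels, batch_size):
    losses, dices = [], []
    k = model.spec.n_classes
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], labels[i : i + batch_size]
        logits = model.forward(xb, train=False)
        w1 = np.ones(yb.shape, dtype=float)
        loss, _ = _segmentation_loss_and_grad(logits, yb, w1)
        losses.append(loss * len(xb))
        pred = np.argmax(logits, axis=1)
        dices.extend(mean_dice(pred[j], yb[j], k) for j in range(len(xb)))
    return float(np.sum(losses) / len(x)), float(np.nanmean(dices))


def _eval_classifier(model, x, y, batch_size):
    losses, preds = [], []
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward(xb, train=False)
        onehot = np.eye(logits.shape[1])[yb]
        loss, _ = _classification_loss_and_grad(logits, onehot)
        losses.append(loss * len(xb))
        preds.extend(np.argmax(logits, axis=1))
    return float(np.sum(losses) / len(x)), categorical_accuracy(preds, y)


def train(
    model,
    train_data: tuple,
    val_data: tuple | None,
    config: TrainConfig,
    task: str = "segmentation",
    weight_maps: np.ndarray | None = None,
    verbose: bool = False,
):
    """Train a classifier or segmenter; returns (model, history DataFrame).

    ``train_data``/``val_data`` are (images, targets): integer label maps for
    segmentation, integer class indices for classification.  For segmentation
    ``weight_maps`` (one per training image, precomputed on the augmented
    labels) multiply the per-pixel cross-entropy; validation loss is always
    unweighted so the plateau schedule tracks a fixed objective.
    """
    if task not in ("segmentation", "classification"):
        raise ValueError(f"unknown task {task!r}")
    x_tr = _as_batch_images(train_data[0])
    y_tr = np.asarray(train_data[1])
    if len(x_tr) == 0:
        raise ValueError("empty training set")
    if task == "segmentation":
        wm = (
            np.ones(y_tr.shape, dtype=float)
            if weight_maps is None
            else np.asarray(weight_maps, dtype=float)
        )
        if wm.shape != y_tr.shape:
            raise ValueError("weight_maps must match training label shape")
    rng = np.random.default_rng(config.seed)
    model.dropout.rng = np.random.default_rng(config.seed + 1)
    opt = AMSGrad(model, lr=config.lr, l2=config.l2_factor)
    sched = ReduceLROnPlateau(
        opt, factor=config.plateau_factor, patience=config.plateau_patience
    )
    rows = []
    bs = config.batch_size
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        metric_acc: list[float] = []
        for i in range(0, len(order), bs):
            idx = order[i : i + bs]
            xb = x_tr[idx]
            model.zero_grads()
            logits = model.forward(xb, train=True)
            if task == "segmentation":
                loss, grad = _segmentation_loss_and_grad(logits, y_tr[idx], wm[idx])
                pred = np.argmax(logits, axis=1)
                k = logits.shape[1]
                metric_acc.extend(
                    mean_dice(pred[j], y_tr[idx][j], k) for j in range(len(idx))
                )
            else:
                onehot = np.eye(logits.shape[1])[y_tr[idx]]
                loss, grad = _classification_loss_and_grad(logits, onehot)
                metric_acc.extend(
                    (np.argmax(logits, axis=1) == y_tr[idx]).astype(float)
                )
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {i // bs} (lr={opt.lr:g})"
                )
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        epoch_loss = epoch_loss / len(x_tr) + opt.penalty()

        # training metrics accumulate over the epoch's batches in train mode
        # (batch statistics), matching the usual deep-learning history curves
        row = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_obj": epoch_loss,
            "train_loss": epoch_loss,
            "train_metric": float(np.nanmean(metric_acc)),
        }
        evaluate = _eval_segmenter if task == "segmentation" else _eval_classifier
        if val_data is not None:
            x_va = _as_batch_images(val_data[0])
            va_loss, va_metric = evaluate(model, x_va, np.asarray(val_data[1]), bs)
            row.update(val_loss=va_loss, val_metric=va_metric)
            sched.step(va_loss)
        else:
            sched.step(epoch_loss)
        rows.append(row)
        if verbose:
            print(
                f"epoch {epoch:3d}  lr {opt.lr:.5f}  loss {row['train_loss']:.4f}  "
                f"metric {row['train_metric']:.4f}"
                + (f"  val {row.get('val_metric', float('nan')):.4f}" if val_data else "")
            )
    return model, pd.DataFrame(rows)


@dataclass
class Trial:
    config: dict
    epochs: int
    score: float
    bracket: int
    rung: int


def hyperband_search(
    objective,
    space: list[dict],
    max_epochs: int = 20,
    eta: int = 3,
    seed: int = 0,
):
    """Hyperband over a discrete configuration space.

    ``objective(config, n_epochs)`` trains a fresh model for ``n_epochs`` and
    returns a validation score (higher is better).  Runs the standard
    successive-halving brackets with reduction factor ``eta`` and maximum
    per-configuration budget ``max_epochs``; returns (best config, trial log).
    """
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    s_max = int(math.log(max_epochs, eta))
    log: list[Trial] = []
    best_cfg, best_score = None, -np.inf
    for s in range(s_max, -1, -1):
        n = int(math.ceil((s_max + 1) / (s + 1) * eta**s))
        r = max_epochs * eta ** (-s)
        idx = rng.choice(len(space), size=min(n, len(space)), replace=len(space) < n)
        configs = [dict(space[i]) for i in idx]
        for rung in range(s + 1):
            n_i = max(1, int(n * eta ** (-rung)))
            r_i = max(1, int(round(r * eta**rung)))
            scored = []
            for cfg in configs[:n_i]:
                score = objective(cfg, r_i)
                scored.append((score, cfg))
                log.append(Trial(cfg, r_i, score, s, rung))
                if score > best_score:
                    best_score, best_cfg = score, cfg
            scored.sort(key=lambda t: t[0], reverse=True)
            keep = max(1, int(n_i / eta))
            configs = [cfg for _, cfg in scored[:keep]]
    trial_log = pd.DataFrame(
        [{"bracket": t.bracket, "rung": t.rung, "epochs": t.epochs, "score": t.score,
          **{f"cfg_{k}": v for k, v in t.config.items()}} for t in log]
    )
    return best_cfg, trial_log
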