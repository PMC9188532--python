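"""Loss functions and evaluation metrics.

Classification: categorical cross-entropy -sum_i gt_i log(sf_i) and
categorical accuracy.  Segmentation: the weighted cross-entropy

    L = -sum_{x in Omega} w(x) log(p_{l(x)}(x))

summed over pixels of one image (then averaged over the mini-batch during
training), and the Dice similarity coefficient DSC = 2TP / (FP + 2TP + FN).
Probabilities are floored at EPS = 1e-7 before the log.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EPS",
    "categorical_cross_entropy",
    "weighted_cross_entropy",
    "confusion_counts",
    "dice_coefficient",
    "mean_dice",
    "categorical_accuracy",
]

EPS = 1e-7


def categorical_cross_entropy(sf: np.ndarray, gt: np.ndarray) -> float:
    """-sum_i gt_i log(sf_i); batched inputs return the batch mean."""
    sf = np.clip(np.asarray(sf, dtype=float), EPS, None)
    gt = np.asarray(gt, dtype=float)
    if sf.shape != gt.shape:
        raise ValueError(f"shape mismatch {sf.shape} vs {gt.shape}")
    per_sample = -np.sum(gt * np.log(sf), axis=-1)
    return float(np.mean(per_sample))


def weighted_cross_entropy(
    prob_map: np.ndarray, labels: np.ndarray, weight_map: np.ndarray
) -> float:
    """Weighted cross-entropy summed over all pixels of one image.

    ``prob_map`` has shape (H, W, n_classes) with per-pixel softmax rows,
    ``labels`` and ``weight_map`` are (H, W).
    """
    prob_map = np.asarray(prob_map, dtype=float)
    labels = np.asarray(labels)
    weight_map = np.asarray(weight_map, dtype=float)
    if prob_map.shape[:2] != labels.shape or labels.shape != weight_map.shape:
        raise ValueError(
            f"shape mismatch: probs {prob_map.shape}, labels {labels.shape}, "
            f"weights {weight_map.shape}"
        )
    if labels.max(initial=0) >= prob_map.shape[2]:
        raise ValueError("label value out of range for probability map")
    rr, cc = np.indices(labels.shape)
    p_true = np.clip(prob_map[rr, cc, labels], EPS, None)
    return float(-np.sum(weight_map * np.log(p_true)))


def confusion_counts(pred: np.ndarray, truth: np.ndarray, cls: int) -> tuple[int, int, int]:
    """(TP, FP, FN) pixel counts for one class."""
    p = np.asarray(pred) == cls
    t = np.asarray(truth) == cls
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    return tp, fp, fn


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, cls: int) -> float:
    """DSC = 2TP / (FP + 2TP + FN) for one class; NaN if class absent from both."""
    if np.asarray(pred).shape != np.asarray(truth).shape:
        raise ValueError("pred and truth must share a shape")
    tp, fp, fn = confusion_counts(pred, truth, cls)
    denom = fp + 2 * tp + fn
    if denom == 0:
        return float("nan")  # 0/0: class absent everywhere, skipped in means
    return 2.0 * tp / denom


def mean_dice(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> float:
    """Unweighted mean DSC over foreground classes present in pred or truth."""
    scores = [dice_coefficient(pred, truth, c) for c in range(1, n_classes)]
    scores = [s for s in scores if not np.isnan(s)]
    return float(np.mean(scores)) if scores else float("nan")


def categorical_accuracy(pred, truth) -> float:
    """Fraction of predictions matching the ground truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a shape")
    if pred.size == 0:
        raise ValueError("empty inputs")
    return float(np.mean(pred == truth))
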