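"""Closed forms and oracles for losses and evaluation metrics."""

import numpy as np
import pytest

from myoseg.losses_metrics import (
    categorical_accuracy,
    categorical_cross_entropy,
    dice_coefficient,
    mean_dice,
    weighted_cross_entropy,
)
from myoseg.nn.core import softmax
from myoseg.training import _segmentation_loss_and_grad


@pytest.mark.parametrize(
    "sf,gt,expected",
    [
        ((1.0, 0.0), (1.0, 0.0), 0.0),
        ((0.5, 0.5), (1.0, 0.0), np.log(2)),
        ((0.25, 0.75), (0.0, 1.0), -np.log(0.75)),
    ],
)
def test_categorical_cross_entropy_closed_forms(sf, gt, expected):
    assert categorical_cross_entropy(np.array(sf), np.array(gt)) == pytest.approx(
        expected, abs=1e-6
    )


def test_batch_mean_equals_mean_of_samples(rng):
    sf = softmax(rng.normal(size=(6, 2)), axis=1)
    gt = np.eye(2)[rng.integers(0, 2, 6)]
    per = [categorical_cross_entropy(sf[i], gt[i]) for i in range(6)]
    assert categorical_cross_entropy(sf, gt) == pytest.approx(np.mean(per), rel=1e-12)


def _scalar_loop_wce(prob, labels, w):
    total = 0.0
    for i in range(labels.shape[0]):
        for j in range(labels.shape[1]):
            total -= w[i, j] * np.log(max(prob[i, j, labels[i, j]], 1e-7))
    return total


def test_weighted_ce_matches_scalar_loop_oracle(rng):
    prob = softmax(rng.normal(size=(4, 4, 3)), axis=-1)
    labels = rng.integers(0, 3, (4, 4))
    w = rng.uniform(0.5, 5.0, (4, 4))
    assert weighted_cross_entropy(prob, labels, w) == pytest.approx(
        _scalar_loop_wce(prob, labels, w), rel=1e-6
    )


def test_weighted_ce_unit_weights_reduce_to_ce_sum(rng):
    prob = softmax(rng.normal(size=(3, 3, 4)), axis=-1)
    labels = rng.integers(0, 4, (3, 3))
    w = np.ones((3, 3))
    expected = sum(
        categorical_cross_entropy(prob[i, j], np.eye(4)[labels[i, j]])
        for i in range(3)
        for j in range(3)
    )
    assert weighted_cross_entropy(prob, labels, w) == pytest.approx(expected, rel=1e-9)


def test_weighted_ce_perfect_prediction_zero():
    labels = np.array([[0, 1], [2, 1]])
    prob = np.eye(3)[labels]
    assert weighted_cross_entropy(prob, labels, np.full((2, 2), 3.0)) == 0.0


def test_weighted_ce_linear_in_weights(rng):
    prob = softmax(rng.normal(size=(4, 4, 3)), axis=-1)
    labels = rng.integers(0, 3, (4, 4))
    w = rng.uniform(0.5, 2.0, (4, 4))
    assert weighted_cross_entropy(prob, labels, 3.0 * w) == pytest.approx(
        3.0 * weighted_cross_entropy(prob, labels, w), rel=1e-12
    )


def test_weighted_ce_shape_mismatch():
    with pytest.raises(ValueError):
        weighted_cross_entropy(np.ones((2, 2, 3)) / 3, np.zeros((3, 3), int), np.ones((2, 2)))


def test_loss_gradient_matches_finite_differences(rng):
    """Analytic d(loss)/d(logits) on a 2x2 toy map vs central differences."""
    logits = rng.normal(size=(1, 3, 2, 2))
    labels = rng.integers(0, 3, (1, 2, 2))
    w = rng.uniform(0.5, 2.0, (1, 2, 2))
    _, grad = _segmentation_loss_and_grad(logits, labels, w)
    eps = 1e-6
    for c in range(3):
        for i in range(2):
            for j in range(2):
                lp = logits.copy()
                lp[0, c, i, j] += eps
                lm = logits.copy()
                lm[0, c, i, j] -= eps
                num = (
                    _segmentation_loss_and_grad(lp, labels, w)[0]
                    - _segmentation_loss_and_grad(lm, labels, w)[0]
                ) / (2 * eps)
                assert num == pytest.approx(grad[0, c, i, j], rel=1e-4, abs=1e-8)


@pytest.mark.parametrize(
    "tp,fp,fn,expected",
    [(2, 1, 1, 2 / 3), (5, 0, 0, 1.0), (0, 3, 2, 0.0)],
)
def test_dice_from_confusion_counts(tp, fp, fn, expected):
    pred = np.zeros(tp + fp + fn + 2, dtype=int)
    truth = np.zeros_like(pred)
    pred[:tp] = truth[:tp] = 1
    pred[tp : tp + fp] = 1
    truth[tp + fp : tp + fp + fn] = 1
    assert dice_coefficient(pred, truth, 1) == pytest.approx(expected)


def test_dice_identical_disjoint_and_symmetry(rng):
    a = rng.integers(0, 3, (8, 8))
    assert dice_coefficient(a, a, 1) == 1.0
    assert dice_coefficient(a, a, 2) == 1.0
    b = np.zeros((4, 4), int)
    b[0] = 1
    c = np.zeros((4, 4), int)
    c[2] = 1
    assert dice_coefficient(b, c, 1) == 0.0
    d = rng.integers(0, 3, (8, 8))
    assert dice_coefficient(a, d, 1) == dice_coefficient(d, a, 1)
    assert 0.0 <= dice_coefficient(a, d, 1) <= 1.0


def test_mean_dice_skips_absent_classes():
    a = np.zeros((4, 4), int)
    a[0] = 1
    assert mean_dice(a, a, n_classes=5) == 1.0  # classes 2..4 absent -> skipped
    assert np.isnan(dice_coefficient(a, a, 3))


@pytest.mark.parametrize(
    "pred,truth,expected",
    [([1, 1, 0], [1, 1, 0], 1.0), ([1, 0], [0, 1], 0.0), ([1, 0, 1, 1], [1, 0, 0, 1], 0.75)],
)
def test_categorical_accuracy(pred, truth, expected):
    assert categorical_accuracy(pred, truth) == expected
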