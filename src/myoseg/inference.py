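"""Tree-structured prediction: classify the district, route to a segmenter.

The inner node classifies the down-sized (128x128) slice as thigh or leg
with the one-hot convention (1, 0) = thigh, (0, 1) = leg; argmax = 0 routes
to the 13-class thigh segmenter, argmax = 1 to the 7-class leg segmenter,
both operating on the full-size slice.  Ties at the argmax resolve to the
lowest index (thigh).  Slices are min-max normalized to [0, 1] before the
networks, and center-padded/cropped with zeros to the segmenter input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .losses_metrics import dice_coefficient, mean_dice
from .networks import Classifier, Segmenter
from .preprocess import downsize_for_classifier

__all__ = ["TreeModel", "classify_district", "segment_slice", "segment_volume"]

DISTRICTS = ("thigh", "leg")


@dataclass
class TreeModel:
    """Classifier plus the two district segmentation networks."""

    classifier: Classifier
    thigh_segmenter: Segmenter
    leg_segmenter: Segmenter

    def __post_init__(self):
        if self.classifier.spec.n_classes != 2:
            raise ValueError("classifier must be binary")

    def segmenter_for(self, district: str) -> Segmenter:
        return self.thigh_segmenter if district == "thigh" else self.leg_segmenter


def _normalize(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    return (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)


def _center_fit(image: np.ndarray, size: int):
    """Center-pad/crop to size x size; returns (fitted, slices to undo)."""
    h, w = image.shape
    out = np.zeros((size, size), dtype=image.dtype)

    def span(n):
        if n >= size:
            a = (n - size) // 2
            return slice(a, a + size), slice(0, size)
        a = (size - n) // 2
        return slice(0, n), slice(a, a + n)

    src_r, dst_r = span(h)
    src_c, dst_c = span(w)
    out[dst_r, dst_c] = image[src_r, src_c]
    return out, (src_r, dst_r, src_c, dst_c)


def classify_district(model: TreeModel, image: np.ndarray) -> tuple[str, np.ndarray]:
    """Return the district call and the 2-vector of class probabilities."""
    image = _normalize(image)
    if min(image.shape) < model.classifier.spec.input_size:
        raise ValueError(
            f"image {image.shape} smaller than classifier input "
            f"{model.classifier.spec.input_size}"
        )
    small = downsize_for_classifier(image, model.classifier.spec.input_size)
    probs = model.classifier.predict_proba(small[None, None])[0]
    if not np.all(np.isfinite(probs)):
        raise FloatingPointError("non-finite classifier output")
    return DISTRICTS[int(np.argmax(probs))], probs


def segment_slice(model: TreeModel, image: np.ndarray, return_probs: bool = False):
    """Classify, route and segment one slice; returns (labels, district[, probs])."""
    district, _ = classify_district(model, image)
    seg = model.segmenter_for(district)
    size = seg.spec.input_size
    norm = _normalize(image)
    fitted, (src_r, dst_r, src_c, dst_c) = _center_fit(norm, size)
    prob = seg.predict_proba(fitted[None, None])[0]  # (K, size, size)
    labels_fit = np.argmax(prob, axis=0).astype(np.int16)
    labels = np.zeros(image.shape, dtype=np.int16)
    labels[src_r, src_c] = labels_fit[dst_r, dst_c]
    if return_probs:
        probs = np.zeros(image.shape + (prob.shape[0],))
        probs[src_r, src_c] = prob.transpose(1, 2, 0)[dst_r, dst_c]
        return labels, district, probs
    return labels, district


def segment_volume(model: TreeModel, volume: np.ndarray, truth: np.ndarray | None = None):
    """Slice-wise segmentation of a (H, W, n_slices) stack.

    Returns (label volume, per-slice report).  With ground truth supplied the
    report carries the per-slice mean DSC over foreground classes and
    per-class DSC columns.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume (H, W, n_slices)")
    out = np.zeros(volume.shape, dtype=np.int16)
    rows = []
    for k in range(volume.shape[2]):
        labels, district = segment_slice(model, volume[:, :, k])
        out[:, :, k] = labels
        row = {"slice": k, "district": district}
        if truth is not None:
            t = truth[:, :, k]
            n_classes = model.segmenter_for(district).spec.n_classes
            row["mean_dsc"] = mean_dice(labels, t, n_classes)
            for c in range(1, n_classes):
                row[f"dsc_class_{c}"] = dice_coefficient(labels, t, c)
        rows.append(row)
    return out, pd.DataFrame(rows)
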