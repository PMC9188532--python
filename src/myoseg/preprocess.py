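"""Label-map cleanup and image down-sizing applied before training/inference.

Manual segmentations registered between sequences carry small speckle
artifacts; these are removed by consecutive area opening and closing with a
4-pixel area threshold.  Classifier inputs are down-sized to 128x128 with
cubic-spline interpolation and anti-aliasing.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = ["clean_mask", "downsize_for_classifier"]

# 8-connectivity for foreground components; holes use the dual 4-connectivity
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def clean_mask(labels: np.ndarray, area_threshold: int = 4) -> np.ndarray:
    """Area opening then closing of a multi-class label map.

    Per foreground class (ascending label order): connected components
    (8-connectivity) with *fewer than* ``area_threshold`` pixels are removed
    to background, then enclosed holes smaller than the threshold inside the
    class region are filled with that class.  Targets speckle left by the
    inter-sequence registration of manual masks.
    """
    if not np.issubdtype(np.asarray(labels).dtype, np.integer):
        raise TypeError("label map must be integer-valued")
    labels = np.asarray(labels)
    out = labels.copy()
    for cls in np.unique(labels):
        if cls == 0:
            continue
        mask = out == cls
        # opening: drop components smaller than the threshold
        comp, n = ndimage.label(mask, structure=_STRUCT8)
        if n:
            sizes = np.bincount(comp.ravel())
            small = np.flatnonzero(sizes < area_threshold)
            small = small[small > 0]
            if small.size:
                out[np.isin(comp, small)] = 0
                mask = out == cls
        # closing: fill enclosed holes smaller than the threshold
        holes, n = ndimage.label(~mask, structure=_STRUCT4)
        if n:
            sizes = np.bincount(holes.ravel())
            border = np.unique(
                np.concatenate([holes[0], holes[-1], holes[:, 0], holes[:, -1]])
            )
            for h in range(1, n + 1):
                if h in border or sizes[h] >= area_threshold:
                    continue
                hmask = holes == h
                # a hole belongs to this class only if fully enclosed by it
                neighbours = ndimage.binary_dilation(hmask, structure=_STRUCT8) & ~hmask
                if np.all(out[neighbours] == cls):
                    out[hmask] = cls
    return out


def downsize_for_classifier(image: np.ndarray, size: int = 128) -> np.ndarray:
    """Down-size an intensity image to ``size`` x ``size`` for classification.

    Cubic-spline interpolation with anti-aliasing pre-smoothing.  Upsampling
    is refused: inputs must be at least ``size`` in both dimensions.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D intensity image")
    if min(image.shape) < size:
        raise ValueError(
            f"input {image.shape} smaller than target {size}x{size}; upsampling refused"
        )
    if image.shape == (size, size):
        return image.copy()
    return resize(image, (size, size), order=3, anti_aliasing=True, preserve_range=True)
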