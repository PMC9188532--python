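"""Stochastic geometric augmentation of annotated limb slices.

Four transformation families, applied (each with independent probability
0.5) in a fixed order per augmented image:

1. independent horizontal/vertical translations of the left and right limb,
   bounded by each limb's shortest distance to the image borders;
2. independent per-limb rotations, angle uniform in [-7, 7] degrees;
3. piecewise-affine warps on a 4x4 control grid, point displacements normal
   with amplitude uniform in [0.1, 1] percent of the image size;
4. elastic deformations: random displacement fields smoothed by a Gaussian
   kernel (SD uniform in [5, 10]) with strength uniform in [0, 20].

Images are resampled with bicubic splines, label maps with nearest
neighbour.  ``build_augmented_dataset`` draws sources uniformly with
replacement until ``target_count`` pairs exist (paper-scale default 5000)
and splits them at random into 90% training / 10% validation (4500/500).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import PiecewiseAffineTransform, warp

from .phantom import AnnotatedSlice

__all__ = [
    "AugmentationConfig",
    "SideSplitError",
    "split_sides",
    "random_side_translation",
    "random_side_rotation",
    "piecewise_affine",
    "elastic",
    "build_augmented_dataset",
]

logger = logging.getLogger(__name__)

#: intensity above which a pixel counts as limb tissue when locating the sides
FOREGROUND_THRESHOLD = 0.1


class SideSplitError(ValueError):
    """The two limbs cannot be separated by a vertical line."""


@dataclass(frozen=True)
class AugmentationConfig:
    """Transform ranges and dataset bookkeeping (defaults as published)."""

    rotation_range: tuple[float, float] = (-7.0, 7.0)
    pw_affine_grid: int = 4
    pw_affine_scale_range: tuple[float, float] = (0.1, 1.0)  # percent of image size
    elastic_strength_range: tuple[float, float] = (0.0, 20.0)
    elastic_kernel_sd_range: tuple[float, float] = (5.0, 10.0)
    target_count: int = 5000
    train_fraction: float = 0.9
    include_prob: float = 0.5
    include_originals: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def _foreground(slc: AnnotatedSlice) -> np.ndarray:
    return (slc.image > FOREGROUND_THRESHOLD) | (slc.labels > 0)


def split_sides(slc: AnnotatedSlice) -> tuple[np.ndarray, np.ndarray]:
    """Binary half-plane masks separating the left and right limb.

    The two largest 8-connected foreground components are located; the split
    column is the midline between their bounding boxes.  Raises
    :class:`SideSplitError` if fewer than two components exist or their
    bounding boxes overlap horizontally (touching limbs).
    """
    fg = _foreground(slc)
    comp, n = ndimage.label(fg, structure=np.ones((3, 3), bool))
    if n < 2:
        raise SideSplitError(f"expected two limb components, found {n}")
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    two = np.argsort(sizes)[-2:]
    boxes = []
    for lab in two:
        cols = np.where(comp == lab)[1]
        boxes.append((cols.min(), cols.max()))
    boxes.sort()
    if boxes[0][1] >= boxes[1][0]:
        raise SideSplitError("limb bounding boxes overlap horizontally")
    split = (boxes[0][1] + boxes[1][0] + 1) // 2
    cols = np.arange(slc.image.shape[1])
    left = np.zeros_like(fg)
    left[:, :split] = True
    return left, ~left


def _replace(slc: AnnotatedSlice, image, labels) -> AnnotatedSlice:
    return AnnotatedSlice(
        image=image,
        labels=labels.astype(slc.labels.dtype),
        district=slc.district,
        severity=slc.severity,
        provenance=dict(slc.provenance),
    )


def _per_side_transform(slc: AnnotatedSlice, side_params) -> AnnotatedSlice:
    """Apply an affine map (shift and/or rotation) independently per side.

    ``side_params`` maps a half-plane mask to (matrix, offset) for
    ``ndimage.affine_transform`` (output->input convention).
    """
    fg = _foreground(slc)
    bg_fill = float(np.median(slc.image[~fg])) if (~fg).any() else 0.0
    canvas = np.full_like(slc.image, bg_fill)
    new_labels = np.zeros_like(slc.labels)
    for side_mask, (matrix, offset) in side_params:
        region = fg & side_mask
        img_side = np.where(region, slc.image, bg_fill)
        lab_side = np.where(region, slc.labels, 0)
        img_t = ndimage.affine_transform(
            img_side, matrix, offset=offset, order=3, cval=bg_fill, mode="constant"
        )
        lab_t = ndimage.affine_transform(
            lab_side, matrix, offset=offset, order=0, cval=0, mode="constant"
        )
        reg_t = (
            ndimage.affine_transform(
                region.astype(np.uint8), matrix, offset=offset, order=0, cval=0,
                mode="constant",
            )
            > 0
        )
        canvas[reg_t] = img_t[reg_t]
        new_labels[reg_t] = lab_t[reg_t]
    return _replace(slc, canvas, new_labels)


def random_side_translation(slc: AnnotatedSlice, rng: np.random.Generator) -> AnnotatedSlice:
    """Translate each limb independently; offsets uniform in [-D, D] where D
    is that limb's shortest distance to any image border (D = 0 gives the
    identity for that side, so no foreground pixel ever leaves the canvas)."""
    h, w = slc.image.shape
    fg = _foreground(slc)
    params = []
    for side_mask in split_sides(slc):
        region = fg & side_mask
        rr, cc = np.where(region)
        d = int(min(rr.min(), cc.min(), h - 1 - rr.max(), w - 1 - cc.max()))
        dr, dc = (rng.uniform(-d, d), rng.uniform(-d, d)) if d > 0 else (0.0, 0.0)
        # output->input: subtract the shift
        params.append((side_mask, (np.eye(2), np.array([-dr, -dc]))))
    return _per_side_transform(slc, params)


def random_side_rotation(slc: AnnotatedSlice, rng: np.random.Generator,
                         angle_range=(-7.0, 7.0)) -> AnnotatedSlice:
    """Rotate each limb independently about its centroid, angles in degrees
    uniform over ``angle_range``."""
    fg = _foreground(slc)
    params = []
    for side_mask in split_sides(slc):
        region = fg & side_mask
        rr, cc = np.where(region)
        center = np.array([rr.mean(), cc.mean()])
        theta = np.deg2rad(rng.uniform(*angle_range))
        ca, sa = np.cos(theta), np.sin(theta)
        matrix = np.array([[ca, -sa], [sa, ca]])  # inverse rotation (output->input)
        offset = center - matrix @ center
        params.append((side_mask, (matrix, offset)))
    return _per_side_transform(slc, params)


def piecewise_affine(slc: AnnotatedSlice, rng: np.random.Generator,
                     grid: int = 4, scale_range=(0.1, 1.0)) -> AnnotatedSlice:
    """Piecewise-affine warp on a ``grid`` x ``grid`` control-point lattice.

    Each control point moves by a normal displacement with SD = a percent of
    the image size, the percentage drawn once per image from ``scale_range``.
    """
    h, w = slc.image.shape
    rows = np.linspace(0, h - 1, grid)
    cols = np.linspace(0, w - 1, grid)
    src = np.stack(np.meshgrid(cols, rows), axis=-1).reshape(-1, 2)  # (x, y) pairs
    scale = rng.uniform(*scale_range)
    sd = scale / 100.0 * np.array([w, h])
    dst = src + rng.normal(0.0, 1.0, src.shape) * sd
    if np.allclose(src, dst):
        return _replace(slc, slc.image.copy(), slc.labels.copy())
    if hasattr(PiecewiseAffineTransform, "from_estimate"):
        tform = PiecewiseAffineTransform.from_estimate(src, dst)
    else:  # scikit-image < 0.26
        tform = PiecewiseAffineTransform()
        tform.estimate(src, dst)
    image = warp(slc.image, tform, order=3, cval=0.0, preserve_range=True)
    labels = warp(slc.labels, tform, order=0, cval=0, preserve_range=True)
    return _replace(slc, image, labels)


def smooth_displacement(raw: np.ndarray, kernel_sd: float, strength: float) -> np.ndarray:
    """Gaussian-smooth a raw displacement field and scale its peak to ``strength``."""
    f = ndimage.gaussian_filter(raw, kernel_sd)
    peak = np.abs(f).max()
    return f * (strength / peak) if peak > 0 else f


def elastic(slc: AnnotatedSlice, rng: np.random.Generator,
            strength_range=(0.0, 20.0), kernel_sd_range=(5.0, 10.0)) -> AnnotatedSlice:
    """Elastic deformation: uniform random displacement fields smoothed by a
    Gaussian kernel (SD drawn from ``kernel_sd_range``), peak displacement
    drawn from ``strength_range`` pixels."""
    shape = slc.image.shape
    sd = rng.uniform(*kernel_sd_range)
    strength = rng.uniform(*strength_range)
    dr = smooth_displacement(rng.uniform(-1, 1, shape), sd, strength)
    dc = smooth_displacement(rng.uniform(-1, 1, shape), sd, strength)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    coords = [rr + dr, cc + dc]
    image = ndimage.map_coordinates(slc.image, coords, order=3, cval=0.0, mode="constant")
    labels = ndimage.map_coordinates(slc.labels, coords, order=0, cval=0, mode="constant")
    return _replace(slc, image, labels)


def augment_slice(slc: AnnotatedSlice, rng: np.random.Generator,
                  config: AugmentationConfig) -> AnnotatedSlice:
    """Apply a random subset of the four transforms in the fixed order
    translation -> rotation -> piecewise affine -> elastic."""
    out = slc
    try:
        if rng.random() < config.include_prob:
            out = random_side_translation(out, rng)
        if rng.random() < config.include_prob:
            out = random_side_rotation(out, rng, config.rotation_range)
    except SideSplitError as err:
        logger.warning("side-wise transform skipped: %s", err)
    if rng.random() < config.include_prob:
        out = piecewise_affine(out, rng, config.pw_affine_grid, config.pw_affine_scale_range)
    if rng.random() < config.include_prob:
        out = elastic(out, rng, config.elastic_strength_range, config.elastic_kernel_sd_range)
    if out is slc:
        out = _replace(slc, slc.image.copy(), slc.labels.copy())
    return out


def build_augmented_dataset(
    slices: list[AnnotatedSlice], config: AugmentationConfig
) -> tuple[list[AnnotatedSlice], list[AnnotatedSlice]]:
    """Produce ``target_count`` augmented pairs and split train/validation.

    Sources are drawn uniformly with replacement; every transform parameter
    is drawn per image.  The split is a seeded random partition into
    ceil(train_fraction * N) training and the remaining validation pairs.
    """
    if not slices:
        raise ValueError("no source slices provided")
    districts = {s.district for s in slices}
    if len(districts) > 1:
        raise ValueError(f"mixed districts in source slices: {sorted(districts)}")
    master = np.random.default_rng(config.seed)
    out: list[AnnotatedSlice] = []
    if config.include_originals:
        out.extend(slices[: config.target_count])
    while len(out) < config.target_count:
        src = slices[int(master.integers(len(slices)))]
        child = np.random.default_rng(int(master.integers(2**31 - 1)))
        out.append(augment_slice(src, child, config))
    perm = master.permutation(config.target_count)
    n_train = int(np.ceil(config.train_fraction * config.target_count))
    train = [out[i] for i in perm[:n_train]]
    val = [out[i] for i in perm[n_train:]]
    return train, val
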