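"""Geometric augmentation: side splitting, the four transforms, bookkeeping."""

import numpy as np
import pytest

from myoseg.augment import (
    AugmentationConfig,
    SideSplitError,
    build_augmented_dataset,
    elastic,
    piecewise_affine,
    random_side_rotation,
    random_side_translation,
    smooth_displacement,
    split_sides,
)
from myoseg.losses_metrics import dice_coefficient
from myoseg.phantom import AnnotatedSlice, PhantomConfig, generate_dataset


def _mirror(slc):
    return AnnotatedSlice(
        image=slc.image[:, ::-1].copy(),
        labels=slc.labels[:, ::-1].copy(),
        district=slc.district,
        severity=slc.severity,
    )


def test_split_sides_isolates_one_limb(thigh_slice):
    left, right = split_sides(thigh_slice)
    assert not (left & right).any()
    assert (left | right).all()
    # each half carries the full muscle set of exactly one limb
    assert set(np.unique(thigh_slice.labels[left])) == set(range(13))
    assert set(np.unique(thigh_slice.labels[right])) == set(range(13))


def test_split_sides_mirror_swaps(thigh_slice):
    left, right = split_sides(thigh_slice)
    ml, mr = split_sides(_mirror(thigh_slice))
    w = thigh_slice.image.shape[1]
    # mirrored split column mirrors too (within the 1-px parity of flipping)
    assert abs((w - np.sum(ml[0])) - np.sum(right[0])) <= 1


def test_split_sides_touching_limbs_error():
    img = np.zeros((64, 64))
    img[20:44, 8:56] = 0.8  # one merged blob spanning the midline
    lab = np.zeros((64, 64), dtype=np.int16)
    lab[22:42, 10:54] = 1
    s = AnnotatedSlice(image=img, labels=lab, district="leg", severity=0.0)
    with pytest.raises(SideSplitError):
        split_sides(s)


def test_translation_zero_margin_is_identity():
    """A limb touching the border has D = 0 and must not move."""
    img = np.zeros((64, 64))
    img[0:30, 0:20] = 0.8   # left limb touches top and left borders
    img[20:50, 40:60] = 0.8
    lab = np.zeros((64, 64), dtype=np.int16)
    lab[2:28, 2:18] = 1
    lab[22:48, 42:58] = 1
    s = AnnotatedSlice(image=img, labels=lab, district="leg", severity=0.0)
    out = random_side_translation(s, np.random.default_rng(0))
    left, _ = split_sides(s)
    np.testing.assert_array_equal(out.labels[left], s.labels[left])


def test_translation_preserves_label_area(thigh_slice):
    base = (thigh_slice.labels > 0).sum()
    for seed in range(10):
        out = random_side_translation(thigh_slice, np.random.default_rng(seed))
        area = (out.labels > 0).sum()
        assert abs(area - base) / base < 0.02
        assert set(np.unique(out.labels)) <= set(np.unique(thigh_slice.labels))


def test_translation_reproducible(thigh_slice):
    a = random_side_translation(thigh_slice, np.random.default_rng(5))
    b = random_side_translation(thigh_slice, np.random.default_rng(5))
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_array_equal(a.image, b.image)


def test_rotation_zero_angle_identity(leg_slice):
    out = random_side_rotation(leg_slice, np.random.default_rng(0), angle_range=(0.0, 0.0))
    np.testing.assert_array_equal(out.labels, leg_slice.labels)


def test_rotation_near_invertibility(leg_slice):
    """+7 then -7 degrees restores large muscles to Dice >= 0.95."""
    fwd = random_side_rotation(leg_slice, np.random.default_rng(0), angle_range=(7.0, 7.0))
    back = random_side_rotation(fwd, np.random.default_rng(0), angle_range=(-7.0, -7.0))
    counts = np.bincount(leg_slice.labels.ravel(), minlength=7)
    large = [c for c in range(1, 7) if counts[c] >= 100]
    assert large
    for c in large:
        assert dice_coefficient(back.labels, leg_slice.labels, c) >= 0.95


def test_piecewise_affine_zero_scale_identity(leg_slice):
    out = piecewise_affine(leg_slice, np.random.default_rng(0), scale_range=(0.0, 0.0))
    np.testing.assert_array_equal(out.labels, leg_slice.labels)


def test_piecewise_affine_no_new_labels(thigh_slice):
    out = piecewise_affine(thigh_slice, np.random.default_rng(3))
    assert set(np.unique(out.labels)) <= set(np.unique(thigh_slice.labels))
    assert out.labels.shape == thigh_slice.labels.shape


def test_piecewise_affine_displacement_scale(rng):
    """At maximum scale the control-point displacement SD is 1% of the image,
    so draws stay below 1% x size + a 4-sigma tail bound."""
    size = 432
    sd = 1.0 / 100.0 * size
    draws = rng.normal(0.0, sd, 1000)
    assert np.abs(draws).max() <= sd * 4.32 + 4 * sd


def test_elastic_zero_strength_identity(leg_slice):
    out = elastic(leg_slice, np.random.default_rng(1), strength_range=(0.0, 0.0))
    np.testing.assert_array_equal(out.labels, leg_slice.labels)


def test_elastic_smoothing_reduces_roughness(rng):
    raw = rng.uniform(-1, 1, (96, 96))
    def roughness(f):
        gr, gc = np.gradient(f)
        return np.hypot(gr, gc).mean()
    f5 = smooth_displacement(raw, 5.0, 10.0)
    f10 = smooth_displacement(raw, 10.0, 10.0)
    assert roughness(f10) < roughness(f5)
    assert np.abs(f5).max() == pytest.approx(10.0)


def test_elastic_labels_remain_valid(thigh_slice):
    out = elastic(thigh_slice, np.random.default_rng(2))
    assert out.labels.shape == thigh_slice.labels.shape
    assert set(np.unique(out.labels)) <= set(range(13))
    assert np.issubdtype(out.labels.dtype, np.integer)


def test_build_dataset_split_arithmetic():
    src = generate_dataset(PhantomConfig(district="leg", image_size=64, seed=0), 3, seed=0)
    cfg = AugmentationConfig(target_count=10, seed=1)
    train, val = build_augmented_dataset(src, cfg)
    assert len(train) == 9 and len(val) == 1
    for s in train + val:
        assert s.labels.shape == src[0].labels.shape
        assert set(np.unique(s.labels)) <= set(range(7))


def test_build_dataset_deterministic():
    src = generate_dataset(PhantomConfig(district="leg", image_size=64, seed=0), 2, seed=0)
    cfg = AugmentationConfig(target_count=6, seed=42)
    t1, v1 = build_augmented_dataset(src, cfg)
    t2, v2 = build_augmented_dataset(src, cfg)
    for a, b in zip(t1 + v1, t2 + v2):
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.labels, b.labels)


def test_build_dataset_rejects_empty_and_mixed():
    with pytest.raises(ValueError, match="no source"):
        build_augmented_dataset([], AugmentationConfig(target_count=5))
    thigh = generate_dataset(PhantomConfig(district="thigh", image_size=64, seed=0), 1)
    leg = generate_dataset(PhantomConfig(district="leg", image_size=64, seed=0), 1)
    with pytest.raises(ValueError, match="mixed"):
        build_augmented_dataset(thigh + leg, AugmentationConfig(target_count=5))
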