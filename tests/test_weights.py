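"""Loss weight maps: inverse-frequency class weights and border term."""

import numpy as np
import pytest

from myoseg.phantom import PhantomConfig, generate_dataset
from myoseg.weights import (
    WeightMapParams,
    class_frequency_weights,
    compute_weight_map,
    separation_border_term,
)


def _exhaustive_d1_d2(labels):
    """O(N^2) oracle: per-pixel distances to the two nearest distinct muscle
    classes, minimizing over every pixel of every class."""
    classes = sorted(set(labels.ravel()) - {0})
    h, w = labels.shape
    rr, cc = np.indices((h, w))
    dists = []
    for c in classes:
        pr, pc = np.where(labels == c)
        d = np.sqrt(
            (rr[..., None] - pr[None, None]) ** 2 + (cc[..., None] - pc[None, None]) ** 2
        ).min(axis=2)
        dists.append(d)
    dists = np.sort(np.stack(dists), axis=0)
    return dists[0], dists[1]


def test_inverse_frequency_ratio():
    m = np.zeros((4, 4), dtype=np.int16)
    m[0] = 1  # 4 of 16 pixels -> class 1 at 25%, background 75%
    w = class_frequency_weights([m], n_classes=2)
    assert w[1] / w[0] == pytest.approx(3.0)
    assert w[0] == pytest.approx(1.0)  # background-normalized convention


def test_equal_areas_equal_weights():
    m = np.repeat(np.arange(4, dtype=np.int16), 4).reshape(4, 4)
    w = class_frequency_weights([m], n_classes=4)
    np.testing.assert_allclose(w, w[0])


def test_absent_class_raises_with_name():
    with pytest.raises(ValueError, match=r"\[1, 2\] absent"):
        class_frequency_weights([np.zeros((3, 3), dtype=np.int16)], n_classes=3)


def test_smallest_muscle_gets_largest_weight():
    data = generate_dataset(PhantomConfig(district="thigh", image_size=96, seed=0), 4, seed=0)
    maps = [s.labels for s in data]
    w = class_frequency_weights(maps, n_classes=13)
    counts = sum(np.bincount(m.ravel(), minlength=13) for m in maps)
    assert np.argmax(w) == np.argmin(counts[1:]) + 1
    assert np.all(w > 0)
    # strict monotonicity: rarer class => larger weight
    order = np.argsort(counts)
    assert np.all(np.diff(w[order]) <= 0)


def test_border_term_formula_at_zero_distance():
    """At d1 + d2 = 0 the exponential equals 1, so the term is exactly w0."""
    params = WeightMapParams(w0=10.0, sigma=7.0)
    assert params.w0 * np.exp(-((0.0 + 0.0) ** 2) / (2 * params.sigma**2)) == 10.0
    # pixels sandwiched between two touching muscles approach w0
    m = np.zeros((8, 8), dtype=np.int16)
    m[:, :4] = 1
    m[:, 4:] = 2
    term = separation_border_term(m, params)
    assert term.max() == pytest.approx(10.0 * np.exp(-1.0 / (2 * 49)), rel=1e-12)


def test_single_muscle_map_term_zero():
    m = np.zeros((8, 8), dtype=np.int16)
    m[2:5, 2:5] = 1
    assert np.all(separation_border_term(m, WeightMapParams()) == 0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_distance_transform_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    m = np.zeros((16, 16), dtype=np.int16)
    for c in (1, 2, 3):
        r0, c0 = rng.integers(0, 12, 2)
        m[r0 : r0 + 4, c0 : c0 + 4] = c
    if len(set(m.ravel()) - {0}) < 2:
        pytest.skip("degenerate draw")
    params = WeightMapParams(w0=10.0, sigma=7.0)
    d1, d2 = _exhaustive_d1_d2(m)
    expected = params.w0 * np.exp(-((d1 + d2) ** 2) / (2 * params.sigma**2))
    np.testing.assert_allclose(separation_border_term(m, params), expected, atol=1e-9)


def test_weight_map_composition_and_w0_linearity():
    m = np.zeros((12, 12), dtype=np.int16)
    m[2:6, 2:6] = 1
    m[2:6, 8:11] = 2
    cw = class_frequency_weights([m], n_classes=3)
    p1 = WeightMapParams(w0=10.0, sigma=7.0)
    p2 = WeightMapParams(w0=20.0, sigma=7.0)
    w1 = compute_weight_map(m, cw, p1)
    w2 = compute_weight_map(m, cw, p2)
    class_term = cw[m]
    np.testing.assert_allclose(w2 - class_term, 2 * (w1 - class_term), atol=1e-12)
    assert np.all(w1 >= cw.min() - 1e-12)
    assert np.all(np.isfinite(w1))


def test_far_from_borders_reduces_to_class_weight():
    m = np.zeros((80, 80), dtype=np.int16)
    m[2:6, 2:6] = 1
    m[2:6, 74:78] = 2
    cw = class_frequency_weights([m], n_classes=3)
    w = compute_weight_map(m, cw, WeightMapParams(w0=10.0, sigma=7.0))
    # far corner: d1+d2 >> sigma
    assert w[79, 40] == pytest.approx(cw[0], abs=1e-6)


def test_mirror_symmetry():
    m = np.zeros((10, 14), dtype=np.int16)
    m[2:5, 2:5] = 1
    m[6:9, 8:12] = 2
    params = WeightMapParams()
    t = separation_border_term(m, params)
    t_mirror = separation_border_term(m[:, ::-1], params)
    np.testing.assert_allclose(t[:, ::-1], t_mirror, atol=1e-12)


def test_missing_class_weight_rejected():
    m = np.full((4, 4), 3, dtype=np.int16)
    with pytest.raises(ValueError, match="class 3"):
        compute_weight_map(m, np.ones(2), WeightMapParams())


def test_corridors_carry_top_weights(clean_thigh_slice):
    """The narrow background corridors between muscles hold the largest
    weight-map values on a realistic phantom."""
    labels = clean_thigh_slice.labels
    cw = class_frequency_weights([labels], n_classes=13)
    w = compute_weight_map(labels, cw, WeightMapParams(w0=10.0, sigma=7.0))
    top = w >= np.percentile(w, 99.5)
    # top-percentile pixels are dominated by the border term, i.e. well above
    # any pure class weight of the pixels they sit on
    assert np.all(w[top] > cw[labels[top]] + 5.0)
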