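"""Architecture contracts and the receptive-field design."""

import numpy as np
import pytest

from myoseg.networks import (
    BlockSpec,
    Classifier,
    Segmenter,
    _RBl,
    classifier_blocks,
    classifier_spec,
    receptive_fields,
    segmenter_blocks,
    segmenter_spec,
)

TABLE_RF = [
    (1, 3, 5),
    (6, 10, 14),
    (16, 24, 32),
    (36, 52, 68),
    (76, 108, 140),
    (188, 284, 380),
]


def test_receptive_fields_published_progression():
    assert receptive_fields(segmenter_blocks(block6_kernel=4)) == TABLE_RF


def test_receptive_fields_literal_block_label_variant():
    """Reading the sixth block's downsampling kernel literally as 3 gives a
    different, smaller progression (the documented design ambiguity)."""
    assert receptive_fields(segmenter_blocks(block6_kernel=3))[5] == (172, 268, 364)


def test_receptive_fields_rejects_expanding_blocks():
    with pytest.raises(ValueError):
        receptive_fields([BlockSpec(8, 2, 2, side="expanding")])


def test_receptive_field_matches_gradient_footprint(rng):
    """Empirical oracle: on an all-linear two-block contracting stack, the
    input support of one output unit's gradient spans the computed field."""
    blocks = classifier_blocks()[:2]
    rf = receptive_fields(blocks)[-1][-1]  # 14
    b1 = _RBl(1, 2, blocks[0].k1, blocks[0].s1, rng, activation=None)
    b2 = _RBl(2, 3, blocks[1].k1, blocks[1].s1, rng, activation=None)
    size = 40
    x = rng.standard_normal((1, 1, size, size))
    h = b2.forward(b1.forward(x, train=False), train=False)
    center = h.shape[2] // 2
    dout = np.zeros_like(h)
    dout[0, 0, center, center] = 1.0
    b1.zero_grads(), b2.zero_grads()
    dx = b1.backward(b2.backward(dout))
    rows = np.where(np.abs(dx[0, 0]).max(axis=1) > 1e-12)[0]
    cols = np.where(np.abs(dx[0, 0]).max(axis=0) > 1e-12)[0]
    assert rows.max() - rows.min() + 1 == rf
    assert cols.max() - cols.min() + 1 == rf


def test_classifier_output_is_probability_pair(rng):
    spec = classifier_spec(input_size=64, width_multiplier=0.125)
    clf = Classifier(spec, seed=0)
    p = clf.predict_proba(rng.random((3, 1, 64, 64)))
    assert p.shape == (3, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p >= 0).all()


def test_classifier_spatial_dims_halve_per_block(rng):
    spec = classifier_spec(input_size=128, width_multiplier=1 / 16)
    clf = Classifier(spec, seed=0)
    x = rng.random((1, 1, 128, 128))
    dims = []
    for blk in clf.blocks:
        x = blk.forward(x, train=False)
        dims.append(x.shape[2])
    assert dims == [128, 64, 32, 16, 8]


def test_width_multiplier_shrinks_parameters():
    full = Classifier(classifier_spec(input_size=64, width_multiplier=1.0), seed=0)
    eighth = Classifier(classifier_spec(input_size=64, width_multiplier=0.125), seed=0)

    def conv_params(model):
        return sum(
            leaf.params["W"].size
            for leaf in model.leaves()
            if "W" in leaf.params and leaf.params["W"].ndim == 2 and leaf is not model.dense
        )

    ratio = conv_params(full) / conv_params(eighth)
    assert 50 < ratio <= 64.5


def test_segmenter_contracting_dims_and_output(rng):
    spec = segmenter_spec("leg", input_size=96, width_multiplier=1 / 16)
    seg = Segmenter(spec, seed=0)
    x = rng.random((1, 1, 96, 96))
    dims = []
    h = seg.dropout.forward(x, train=False)
    for blk in seg.down:
        h = blk.forward(h, train=False)
        dims.append(h.shape[2])
    assert dims == [96, 48, 24, 12, 6, 2]  # strides 1,2,2,2,2,3
    prob = seg.predict_proba(x)
    assert prob.shape == (1, 7, 96, 96)
    np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-6)
    assert (prob >= 0).all()


def test_segmenter_rejects_indivisible_input():
    with pytest.raises(ValueError, match="not divisible"):
        Segmenter(segmenter_spec("leg", input_size=100, width_multiplier=0.125))


def test_forward_deterministic_in_eval_mode(rng):
    seg = Segmenter(segmenter_spec("leg", input_size=48, width_multiplier=1 / 16), seed=3)
    x = rng.random((2, 1, 48, 48))
    np.testing.assert_array_equal(seg.predict_proba(x), seg.predict_proba(x))


def test_tiny_segmenter_overfits_two_slices():
    """A width-reduced segmenter fits a 2-slice batch to near-perfect Dice,
    the standard sanity check that the architecture and gradients can learn."""
    from myoseg.losses_metrics import mean_dice
    from myoseg.pipeline import make_segmentation_data
    from myoseg.training import TrainConfig, train

    data = make_segmentation_data("leg", 2, 96, seed=0)
    spec = segmenter_spec("leg", input_size=96, width_multiplier=0.125)
    model = Segmenter(spec, seed=0)
    cfg = TrainConfig(lr=0.02, batch_size=2, dropout_rate=0.0, l2_factor=0.0,
                      epochs=150, seed=0)
    x, y = data["x_train"], data["y_train"]
    model, hist = train(model, (x, y), None, cfg, task="segmentation",
                        weight_maps=data["weight_maps"])
    pred = model.predict_labels(x[:, None])
    dscs = [mean_dice(pred[i], y[i], 7) for i in range(len(y))]
    assert np.mean(dscs) >= 0.95
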