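"""End-to-end glue: phantom data -> augmentation -> weight maps -> training.

These helpers wire the pipeline together at configurable (typically reduced)
scale: generate synthetic slices, build the augmented train/validation sets,
precompute loss weight maps on the augmented labels, train the classifier
and segmenters independently, and assemble the routed tree model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .augment import AugmentationConfig, build_augmented_dataset
from .config import RunConfig
from .inference import TreeModel
from .networks import Classifier, Segmenter, classifier_spec, segmenter_spec
from .phantom import PhantomConfig, generate_dataset
from .training import TrainConfig, hyperband_search, train
from .weights import WeightMapParams, class_frequency_weights, compute_weight_map

__all__ = [
    "make_classification_data",
    "make_segmentation_data",
    "train_classifier_on_phantoms",
    "train_segmenter_on_phantoms",
    "train_tree_on_phantoms",
    "hyperband_on_phantoms",
    "flatten_tree_state",
    "load_tree_model",
]


def make_classification_data(n_per_district: int, image_size: int, seed: int,
                             severity_range=(0.0, 0.7)):
    """Balanced thigh/leg phantom set for the district classifier.

    Returns (images, district indices) with the one-hot convention
    thigh -> 0, leg -> 1.
    """
    xs, ys = [], []
    for label, district in enumerate(("thigh", "leg")):
        cfg = PhantomConfig(district=district, image_size=image_size, seed=seed + label)
        for s in generate_dataset(cfg, n_per_district, seed=seed + label,
                                  severity_range=severity_range):
            xs.append(s.image)
            ys.append(label)
    return np.asarray(xs), np.asarray(ys)


def make_segmentation_data(district: str, n: int, image_size: int, seed: int,
                           augment_to: int | None = None,
                           severity_range=(0.0, 0.7), w0: float = 10.0):
    """Phantom slices (optionally augmented) plus class weights and weight maps.

    Returns dict with train/val image and label arrays, per-train-slice
    weight maps (computed after augmentation, since warping changes border
    geometry) and the class-weight vector.
    """
    cfg = PhantomConfig(district=district, image_size=image_size, seed=seed)
    sources = generate_dataset(cfg, n, seed=seed, severity_range=severity_range)
    if augment_to:
        aug_cfg = AugmentationConfig(target_count=augment_to, seed=seed)
        train_s, val_s = build_augmented_dataset(sources, aug_cfg)
    else:
        k = max(1, int(round(0.9 * n)))
        train_s, val_s = sources[:k], sources[k:] or sources[:1]
    n_classes = cfg.n_classes
    cw = class_frequency_weights([s.labels for s in train_s], n_classes)
    params = WeightMapParams.for_district(district, w0=w0)
    wmaps = np.stack([compute_weight_map(s.labels, cw, params) for s in train_s])
    return {
        "x_train": np.asarray([s.image for s in train_s]),
        "y_train": np.asarray([s.labels for s in train_s]),
        "x_val": np.asarray([s.image for s in val_s]),
        "y_val": np.asarray([s.labels for s in val_s]),
        "weight_maps": wmaps,
        "class_weights": cw,
        "n_classes": n_classes,
    }


def train_classifier_on_phantoms(n_per_district: int = 100, image_size: int = 64,
                                 width_multiplier: float = 0.125,
                                 config: TrainConfig | None = None, seed: int = 0,
                                 holdout_fraction: float = 0.2):
    """Train a (width-reduced) district classifier; returns (model, history, heldout)."""
    config = config or TrainConfig(lr=0.002, dropout_rate=0.0, l2_factor=0.0,
                                   epochs=10, seed=seed)
    x, y = make_classification_data(n_per_district, image_size, seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(x))
    n_hold = int(round(holdout_fraction * len(x)))
    hold, keep = perm[:n_hold], perm[n_hold:]
    spec = classifier_spec(input_size=image_size, width_multiplier=width_multiplier,
                           dropout_rate=config.dropout_rate, l2_factor=config.l2_factor)
    model = Classifier(spec, seed=seed)
    model, hist = train(model, (x[keep], y[keep]), (x[hold], y[hold]), config,
                        task="classification")
    return model, hist, (x[hold], y[hold])


def train_segmenter_on_phantoms(district: str = "leg", n: int = 8, image_size: int = 96,
                                width_multiplier: float = 0.25,
                                config: TrainConfig | None = None, seed: int = 0,
                                augment_to: int | None = None, use_weight_maps=True):
    """Train a (width-reduced) segmenter on phantoms; returns (model, history, data)."""
    config = config or TrainConfig(lr=0.015, batch_size=2, dropout_rate=0.0,
                                   l2_factor=0.0, epochs=30, seed=seed)
    data = make_segmentation_data(district, n, image_size, seed, augment_to=augment_to)
    spec = segmenter_spec(district, input_size=image_size,
                          width_multiplier=width_multiplier,
                          dropout_rate=config.dropout_rate, l2_factor=config.l2_factor)
    model = Segmenter(spec, seed=seed)
    model, hist = train(
        model, (data["x_train"], data["y_train"]), (data["x_val"], data["y_val"]),
        config, task="segmentation",
        weight_maps=data["weight_maps"] if use_weight_maps else None,
    )
    return model, hist, data


def train_tree_on_phantoms(cfg: RunConfig):
    """Train classifier + both segmenters at the scale set by ``cfg``."""
    histories = {}
    clf, hist, _ = train_classifier_on_phantoms(
        n_per_district=20, image_size=cfg.classifier_size,
        width_multiplier=cfg.width_multiplier, config=cfg.train, seed=cfg.seed)
    histories["classifier"] = hist
    segs = {}
    for district in ("thigh", "leg"):
        seg, hist, _ = train_segmenter_on_phantoms(
            district=district, n=8, image_size=cfg.image_size,
            width_multiplier=cfg.width_multiplier, config=cfg.train, seed=cfg.seed)
        histories[f"segmenter_{district}"] = hist
        segs[district] = seg
    return TreeModel(clf, segs["thigh"], segs["leg"]), histories


def hyperband_on_phantoms(cfg: RunConfig, max_epochs: int = 20, seed: int = 0,
                          space: list[dict] | None = None):
    """Hyperband over (lr, dr, reg) scored by validation DSC at phantom scale."""
    if space is None:
        space = [
            {"lr": lr, "dropout_rate": dr, "l2_factor": reg}
            for lr in (0.0005, 0.002, 0.009765)
            for dr in (0.0, 0.2, 0.5)
            for reg in (0.0, 0.01, 0.1)
        ]
    data = make_segmentation_data(cfg.district, 8, cfg.image_size, seed)
    spec = segmenter_spec(cfg.district, input_size=cfg.image_size,
                          width_multiplier=cfg.width_multiplier)
    def objective(hp, n_epochs):
        tc = dataclasses.replace(cfg.train, epochs=n_epochs, seed=seed, **hp)
        s = dataclasses.replace(spec, dropout_rate=tc.dropout_rate,
                                l2_factor=tc.l2_factor)
        model = Segmenter(s, seed=seed)
        _, hist = train(model, (data["x_train"], data["y_train"]),
                        (data["x_val"], data["y_val"]), tc, task="segmentation",
                        weight_maps=data["weight_maps"])
        return float(hist["val_metric"].iloc[-1])

    return hyperband_search(objective, space, max_epochs=max_epochs, seed=seed)


def flatten_tree_state(model: TreeModel) -> dict:
    out = {}
    for prefix, net in (("clf", model.classifier), ("thigh", model.thigh_segmenter),
                        ("leg", model.leg_segmenter)):
        for k, v in net.state_dict().items():
            out[f"{prefix}/{k}"] = v
    meta = {
        "clf_size": model.classifier.spec.input_size,
        "seg_size": model.thigh_segmenter.spec.input_size,
        "width": model.classifier.spec.width_multiplier,
    }
    out["meta"] = np.array([meta["clf_size"], meta["seg_size"], meta["width"]])
    return out


def load_tree_model(model_dir: Path) -> TreeModel:
    state = np.load(Path(model_dir) / "model.npz")
    clf_size, seg_size, width = state["meta"]
    clf = Classifier(classifier_spec(int(clf_size), float(width)))
    thigh = Segmenter(segmenter_spec("thigh", int(seg_size), float(width)))
    leg = Segmenter(segmenter_spec("leg", int(seg_size), float(width)))
    for prefix, net in (("clf", clf), ("thigh", thigh), ("leg", leg)):
        sub = {k.split("/", 1)[1]: state[k] for k in state.files if k.startswith(prefix + "/")}
        net.load_state_dict(sub)
    return TreeModel(clf, thigh, leg)
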