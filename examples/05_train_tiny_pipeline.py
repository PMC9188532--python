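"""Train the pipeline end to end at desk scale and route a mixed volume.

Trains a width-reduced district classifier (thigh vs leg phantoms) and a
width-reduced leg segmenter with the distance-weighted cross-entropy, then
runs tree-routed inference on a small mixed stack.  Runtime: a few minutes
on one CPU core.
"""

import numpy as np

from myoseg.inference import TreeModel, segment_volume
from myoseg.losses_metrics import categorical_accuracy
from myoseg.phantom import PhantomConfig, generate_dataset
from myoseg.pipeline import train_classifier_on_phantoms, train_segmenter_on_phantoms
from myoseg.training import TrainConfig

clf_cfg = TrainConfig(lr=0.002, batch_size=5, dropout_rate=0.0, l2_factor=0.0,
                      epochs=6, seed=0)
clf, clf_hist, (x_hold, y_hold) = train_classifier_on_phantoms(
    n_per_district=40, image_size=96, width_multiplier=0.125, config=clf_cfg, seed=0)
pred = np.argmax(clf.predict_proba(x_hold[:, None]), axis=1)
print(f"classifier held-out accuracy: {categorical_accuracy(pred, y_hold):.3f}")

seg, seg_hist, _ = train_segmenter_on_phantoms(district="leg", n=8, image_size=96,
                                               width_multiplier=0.25, seed=0)
print("leg segmenter training DSC by epoch:",
      " ".join(f"{v:.2f}" for v in seg_hist["train_metric"][::5]))

thigh_seg, _, _ = train_segmenter_on_phantoms(district="thigh", n=8, image_size=96,
                                              width_multiplier=0.25, seed=0)
model = TreeModel(classifier=clf, thigh_segmenter=thigh_seg, leg_segmenter=seg)

mixed = (generate_dataset(PhantomConfig(district="thigh", image_size=96, seed=5), 2, seed=5)
         + generate_dataset(PhantomConfig(district="leg", image_size=96, seed=6), 2, seed=6))
vol = np.stack([s.image for s in mixed], axis=2)
truth = np.stack([s.labels for s in mixed], axis=2)
labels, report = segment_volume(model, vol, truth=truth)
print(report[["slice", "district", "mean_dsc"]].to_string(index=False))
# per-slice routing follows the classifier; mean_dsc is the mean Dice over
# the muscles of that district (13 thigh / 7 leg classes)
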