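# Methods

## Problem and model

The package segments individual muscles in 2D lower-limb MRI slices. A
binary classifier assigns each slice an anatomical district (thigh or leg)
from a 128×128 down-sized copy; the full-size slice is then processed by the
district's segmentation network. Districts use the one-hot convention
(1, 0) = thigh, (0, 1) = leg, so argmax 0 routes to the 13-class thigh
segmenter and argmax 1 to the 7-class leg segmenter; exact probability ties
resolve to the lowest index (thigh), a deterministic convention the routing
contract needs.

### Residual blocks

Contracting blocks `RB_l(C, k1, s1, 3, 1)` follow
Convolution–BatchNorm–SkipConnection–Activation: the first convolution
(kernel `k1`, stride `s1`) maps into the block's channel width and its
batch-normalized output is the shortcut; two 3×3 stride-1 convolutions
follow, the shortcut is added after the last batch norm, and the activation
(ReLU; the nonlinearity is a design choice, PReLU would also fit the scheme)
is applied. All convolutions use TensorFlow-style SAME zero padding so
spatial size is governed by stride alone.

Expanding blocks `RB_r` reconstruct resolution: a transposed convolution
(mirroring the kernel/stride of the contracting level: one k=4/s=3 then four
k=2/s=2 steps) followed by batch norm and activation, concatenation with the
same-resolution contracting features, a 1×1 convolution forming the residual
shortcut at the block width, and the same residual 3×3 pair as `RB_l`. The
innermost textual description of the expanding path is not fully specified
anywhere, so this mirrored design is a reconstruction; the final expanding
level keeps 32 channels and stride 1 (all skip levels are consumed by the
five upsampling blocks) before the 1×1 classification convolution and
pixelwise softmax.

### The sixth-block kernel ambiguity

The sixth contracting block is labelled with kernel 3, stride 3, but the
printed receptive-field progression (188/284/380 after fields of 76/108/140
at jump 16) requires (k−1)·16 = 48, i.e. kernel 4; kernel 3 would give
172/268/364. A kernel-4 downsampling convolution also realizes the stated
1/3 downsampling without gaps between sampling windows. The package
defaults to kernel 4 and exposes the literal kernel-3 reading through
`segmenter_blocks(block6_kernel=3)`.

### Classifier feature collection

"All features at the different depth levels collected into a vector" does
not specify the pooling; global average pooling per depth level is used
(32+64+128+256+512 = 992 features at full width) feeding the fully connected
softmax pair. Weights initialize from a Glorot normal distribution.

## Loss and weight maps

Segmentation minimizes L = −Σ_x w(x) log p_{l(x)}(x), summed over the pixels
of one image and averaged over the mini-batch (the sum form keeps the
published w0 = 10 on its intended scale; batch averaging keeps the learning
rate independent of batch size). Probabilities are floored at 1e−7 before
the logarithm.

The weight map is w(x) = w_{l(x)} + w0·exp(−(d1+d2)²/2σ²):

* `w_c` is the inverse pixel frequency of class c over the training set.
  The formula pairs `w_c` with the absolute constant w0, so a scale
  convention is required: weights are normalized so the background weight is
  exactly 1 (configurable). Rarer classes strictly get larger weights.
* `d1`, `d2` are Euclidean distances (pixel units) to the nearest and
  second-nearest *distinct* muscle classes, computed by one exact distance
  transform per class; with fewer than two muscle classes d2 is undefined
  and the border term is zero (the only consistent limit). σ defaults to
  7 px (thigh) and 8 px (leg), chosen to represent the maximum distance
  between neighbouring muscles.
* The term is evaluated at every pixel, as the formula is written: it is
  negligible inside large muscles and peaks (→ w0) both on the background
  corridors separating muscles and on the muscle-edge pixels facing them.
* Weight maps are computed per training slice *after* augmentation, because
  warping changes the border geometry.

Dice similarity uses DSC = 2TP/(FP + 2TP + FN) per class; reported scores
are unweighted means over foreground classes present in prediction or truth
(0/0 classes are skipped), then over slices. Whether background should join
the average is unspecified; foreground-only is the stricter and more common
convention.

## Numpy network core

No deep-learning framework is a dependency: `myoseg.nn` implements Conv2d /
ConvTranspose2d (im2col + matmul, SAME padding), BatchNorm2d (momentum 0.9,
eps 1e−5), Dense, ReLU, pixelwise inverted dropout, global average pooling,
full backpropagation, the AMSGrad optimizer (Adam bias correction folded
into the step size, non-decreasing second moment) and a
reduce-on-plateau schedule (factor 0.5, patience 4: the learning rate halves
on the fourth consecutive epoch without validation-loss improvement). L2
regularization adds the gradient of reg·Σw² on convolution and dense
kernels only (not biases or batch-norm parameters). Arrays are NCHW
float64. The test suite checks every layer and both composite block types
against central finite differences (relative error ≲ 1e−8 on smooth
configurations) and the loss gradient on toy maps to 1e−4.

"Dropout regularization in the input layer" is implemented as pixelwise
dropout on the input image: the input has a single channel, so channel-wise
(spatial) dropout would delete entire images at rate dr rather than
regularize them.

Training metrics in the per-epoch history are accumulated over the epoch's
mini-batches in training mode (batch statistics), the convention of the
major frameworks' history curves; validation metrics use a full pass in
inference mode with running statistics. The plateau schedule tracks the
(unweighted) validation loss so the scheduled objective does not depend on
the weight-map scale.

## Synthetic phantom generator

Each phantom is a 2D slice with two limb cross-sections left/right of the
vertical midline: an elliptical contour with a bright subcutaneous fat ring,
bone discs with dark cortical rim and bright marrow (one femur per thigh
side; tibia + fibula per leg side), and K angular-sector muscle compartments
around the main bone (K = 12 thigh / 6 leg), separated by thin background
fascia gaps and labelled identically on both sides. Muscle compartments are
geometric sectors, not anatomy: the networks need multi-class geometry with
realistic adjacency, not an atlas. Background label 0 covers fat and bone,
matching a muscles-only segmentation protocol that avoids fascia and bone
contours.

Fatty replacement (*severity* ∈ [0, 1]) mixes muscle intensity toward fat
through a smooth logistic-squashed Gaussian random field whose spatial mean
is calibrated to the requested severity by bisection, giving patchy
infiltration; severity 0 emulates a healthy subject and ≥0.6 a severely
fat-replaced one. A smooth multiplicative bias field and additive Gaussian
noise corrupt the image only; intensities are clipped to [0, 1] (the
acquisition protocol's intensity statistics are unknown, so contrast is
chosen for plausibility: fat 0.92, muscle 0.30, marrow 0.85, cortical bone
0.05, background 0.02). Datasets jitter limb position (±2% of image size),
size (scale 0.90–1.02), sector orientation (±0.25 rad) and optionally
severity per slice, with per-slice seeds derived from a master seed.

What the phantom does *not* emulate: real muscle shapes and their
inter-subject variability, partial-volume boundaries, MR physics (no
Dixon/MESE signal model), registration artifacts, or 3D anatomy. Passing
tests therefore demonstrate that the pipeline's mechanics (routing,
optimization, loss geometry, augmentation bookkeeping) behave as designed —
not clinical-grade accuracy on patients.

## Augmentation

Per augmented image a random subset of the four transforms applies in the
fixed order translation → rotation → piecewise affine → elastic; "randomly
applied elements in the following sequence" is read as an independent
Bernoulli(0.5) inclusion per transform (probability configurable). The
augmented set contains only transformed copies; a flag can force-include the
originals. Images resample with bicubic splines, labels with nearest
neighbour; out-of-canvas pixels fill with 0/background.

* Side splitting locates the two largest 8-connected foreground components
  (intensity threshold 0.1 or any labelled pixel) and splits at the midline
  between their bounding boxes; touching limbs raise an error and the
  side-wise transforms are skipped for that draw (with a log entry).
* Translations draw offsets uniformly from [−D, D] per side, D being that
  limb's shortest border distance, so no foreground leaves the canvas and
  D = 0 degenerates to the identity.
* Rotations draw angles uniformly from [−7, 7]° per side about the limb
  centroid.
* Piecewise-affine warps displace a 4×4 control grid by normal draws with
  SD = s% of image size, s ~ U[0.1, 1] per image.
* Elastic deformations smooth uniform noise fields with a Gaussian kernel
  (SD ~ U[5, 10]) and scale the peak displacement to a strength
  ~ U[0, 20] px.

## Scaled study conditions

The full-scale configuration (432×432 slices, 5000 augmented pairs, widths
32→1024, 40 epochs) is impractical for a CPU test suite, so the behavioural
demonstrations run at fixed reduced scale, chosen once:

* district classification: 100 thigh + 100 leg phantoms at 64×64, classifier
  width ×1/8, lr 0.002, batch 5, 8 epochs, 20% held out;
* segmenter training: 8 leg phantoms at 96×96 (96 is the smallest phantom
  size the ×48 stride chain divides), width ×1/4, lr 0.015, batch 2,
  30 epochs, severity jitter 0–0.7;
* overfit sanity check: 2 slices, width ×1/8, lr 0.02, 150 steps;
* augmentation bookkeeping runs at the full 5000-pair default on 64×64
  sources.

Learning rates sit near the upper end of the published search interval
(0.0001–0.01], consistent with the observation that residual preconditioning
tolerates large steps; the tiny-run values were fixed by a brief pilot at
these scales and are defaults of the pipeline helpers, not tuned per test.

## Known limitations

* The numpy core is single-threaded apart from BLAS matmuls; full-scale
  (432×432, width 1) training is out of reach — the full-size architecture
  is validated structurally (shapes, softmax normalization, receptive
  fields) and behaviourally only at reduced width.
* Hyperband's bracket arithmetic follows the standard successive-halving
  formulation with η = 3 (η is unstated in the source design); with small
  discrete spaces configurations may be resampled across brackets.
* `segment_volume` is strictly slice-wise; no 3D consistency is enforced.
* The phantom's severity field raises mean muscle intensity monotonically,
  but real severe infiltration also changes texture and boundary contrast in
  ways the generator does not model.
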