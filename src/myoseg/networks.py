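"""Classification and segmentation network architectures.

Both networks are built from residual blocks following the scheme
Convolution - Batch Normalization - Skip Connection - Activation:

* ``RB_l(C, k1, s1, k2, s2)`` (contracting): a first convolution (kernel k1,
  stride s1) whose batch-normalized output is the shortcut, followed by two
  k2 x k2 stride-s2 convolutions; the shortcut is added after the last batch
  norm, then the activation is applied.
* ``RB_r`` (expanding): a transposed convolution restores spatial resolution,
  the result is concatenated with the same-resolution contracting features,
  and a residual pair of 3x3 convolutions follows.

The classifier stacks 5 RB_l (channels 32..512, halving resolution) on
128x128 inputs, pools the features of every depth level into one vector and
ends in a fully connected 2-way softmax (thigh vs leg).  The segmenters
extend the contracting path with a sixth block (1024 channels, 1/3
downsampling) on 432x432 inputs and mirror it with 6 RB_r, ending in a
1x1 convolution to 13 (thigh) or 7 (leg) classes with pixelwise softmax.

The sixth block's printed receptive fields (188/284/380) imply a kernel-4
downsampling convolution at stride 3, although the block label writes k=3;
the kernel-4 design is the default and the literal k=3 reading is available
via ``block6_kernel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.core import softmax

__all__ = [
    "BlockSpec",
    "NetworkSpec",
    "classifier_blocks",
    "segmenter_blocks",
    "classifier_spec",
    "segmenter_spec",
    "receptive_fields",
    "build_classifier",
    "build_segmenter",
    "Classifier",
    "Segmenter",
]


@dataclass(frozen=True)
class BlockSpec:
    """One residual block: RB_l/RB_r(channels, k1, s1, k2, s2)."""

    channels: int
    k1: int
    s1: int
    k2: int = 3
    s2: int = 1
    side: str = "contracting"

    def __post_init__(self):
        if self.channels < 1 or min(self.k1, self.k2) < 1 or min(self.s1, self.s2) < 1:
            raise ValueError("channels, kernels and strides must be >= 1")
        if self.side not in ("contracting", "expanding"):
            raise ValueError(f"unknown side {self.side!r}")


def classifier_blocks() -> list[BlockSpec]:
    """The five contracting blocks shared by classifier and segmenters."""
    return [
        BlockSpec(32, 1, 1),
        BlockSpec(64, 2, 2),
        BlockSpec(128, 2, 2),
        BlockSpec(256, 2, 2),
        BlockSpec(512, 2, 2),
    ]


def segmenter_blocks(block6_kernel: int = 4) -> list[BlockSpec]:
    """The six contracting blocks of the segmentation networks.

    ``block6_kernel=4`` (default) matches the printed receptive-field
    progression; ``block6_kernel=3`` is the literal block-label reading.
    """
    return classifier_blocks() + [BlockSpec(1024, block6_kernel, 3)]


@dataclass
class NetworkSpec:
    """Input size, block list and training-relevant structural options."""

    input_size: int
    blocks: list[BlockSpec]
    n_classes: int
    width_multiplier: float = 1.0
    dropout_rate: float = 0.0
    l2_factor: float = 0.0

    def scaled_channels(self) -> list[int]:
        return [max(1, round(b.channels * self.width_multiplier)) for b in self.blocks]


def classifier_spec(input_size: int = 128, width_multiplier: float = 1.0,
                    dropout_rate: float = 0.0, l2_factor: float = 0.0) -> NetworkSpec:
    return NetworkSpec(input_size, classifier_blocks(), 2, width_multiplier,
                       dropout_rate, l2_factor)


def segmenter_spec(district: str, input_size: int = 432, width_multiplier: float = 1.0,
                   dropout_rate: float = 0.0, l2_factor: float = 0.0,
                   block6_kernel: int = 4) -> NetworkSpec:
    n_classes = {"thigh": 13, "leg": 7}[district]
    return NetworkSpec(input_size, segmenter_blocks(block6_kernel), n_classes,
                       width_multiplier, dropout_rate, l2_factor)


def receptive_fields(blocks: list[BlockSpec]) -> list[tuple[int, int, int]]:
    """Receptive-field side length after each convolution of each block.

    Standard recursion r_i = r_{i-1} + (k_i - 1) * j_{i-1}, j_i = j_{i-1} * s_i
    with r_0 = j_0 = 1, where j is the cumulative stride (jump).  Returns one
    (after conv1, after conv2, after conv3) triple per contracting block.
    """
    r, j = 1, 1
    out = []
    for b in blocks:
        if b.side != "contracting":
            raise ValueError("receptive fields are defined on the contracting path")
        triple = []
        for k, s in ((b.k1, b.s1), (b.k2, b.s2), (b.k2, b.s2)):
            r = r + (k - 1) * j
            j = j * s
            triple.append(r)
        out.append(tuple(triple))
    return out


class _RBl(nn.Module):
    """Contracting residual block."""

    def __init__(self, cin, cout, k1, s1, rng, activation="relu"):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, k1, s1, rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.conv3 = nn.Conv2d(cout, cout, 3, 1, rng)
        self.bn3 = nn.BatchNorm2d(cout)
        self.act1 = nn.ReLU() if activation == "relu" else None
        self.act2 = nn.ReLU() if activation == "relu" else None
        self.children = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]

    def forward(self, x, train=True):
        h0 = self.bn1.forward(self.conv1.forward(x, train), train)
        h1 = self.bn2.forward(self.conv2.forward(h0, train), train)
        if self.act1 is not None:
            h1 = self.act1.forward(h1, train)
        h2 = self.bn3.forward(self.conv3.forward(h1, train), train)
        out = h2 + h0
        if self.act2 is not None:
            out = self.act2.forward(out, train)
        return out

    def backward(self, dout):
        if self.act2 is not None:
            dout = self.act2.backward(dout)
        g = self.bn3.backward(dout)
        g = self.conv3.backward(g)
        if self.act1 is not None:
            g = self.act1.backward(g)
        g = self.bn2.backward(g)
        g = self.conv2.backward(g)
        gh0 = g + dout
        return self.conv1.backward(self.bn1.backward(gh0))


class _RBr(nn.Module):
    """Expanding residual block: upsample, concat skip, residual conv pair."""

    def __init__(self, cin, skip_c, cout, k, s, rng):
        super().__init__()
        if s > 1:
            self.up = nn.ConvTranspose2d(cin, cout, k, s, rng)
        else:
            self.up = nn.Conv2d(cin, cout, 1, 1, rng)
        self.bn_up = nn.BatchNorm2d(cout)
        self.act_up = nn.ReLU()
        self.skip_c = skip_c
        self.conv1 = nn.Conv2d(cout + skip_c, cout, 1, 1, rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.act1 = nn.ReLU()
        self.conv3 = nn.Conv2d(cout, cout, 3, 1, rng)
        self.bn3 = nn.BatchNorm2d(cout)
        self.act2 = nn.ReLU()
        self.children = [self.up, self.bn_up, self.conv1, self.bn1,
                         self.conv2, self.bn2, self.conv3, self.bn3]

    def forward(self, x, skip, train=True):
        u = self.act_up.forward(self.bn_up.forward(self.up.forward(x, train), train), train)
        cat = np.concatenate([u, skip], axis=1)
        h0 = self.bn1.forward(self.conv1.forward(cat, train), train)
        h1 = self.act1.forward(self.bn2.forward(self.conv2.forward(h0, train), train), train)
        h2 = self.bn3.forward(self.conv3.forward(h1, train), train)
        return self.act2.forward(h2 + h0, train)

    def backward(self, dout):
        dout = self.act2.backward(dout)
        g = self.conv3.backward(self.bn3.backward(dout))
        g = self.act1.backward(g)
        g = self.conv2.backward(self.bn2.backward(g))
        gcat = self.conv1.backward(self.bn1.backward(g + dout))
        cu = gcat.shape[1] - self.skip_c
        gu, gskip = gcat[:, :cu], gcat[:, cu:]
        gx = self.up.backward(self.bn_up.backward(self.act_up.backward(gu)))
        return gx, gskip


class Classifier(nn.Module):
    """District classifier: 5 RB_l, per-level global average pooling, dense softmax."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, activation="relu"):
        super().__init__()
        if len(spec.blocks) != 5:
            raise ValueError("classifier expects exactly 5 contracting blocks")
        if spec.input_size % 16 != 0:
            raise ValueError("classifier input size must be divisible by 16")
        self.spec = spec
        rng = np.random.default_rng(seed)
        chans = spec.scaled_channels()
        self.dropout = nn.Dropout(spec.dropout_rate)
        self.blocks = []
        cin = 1
        for b, c in zip(spec.blocks, chans):
            self.blocks.append(_RBl(cin, c, b.k1, b.s1, rng, activation))
            cin = c
        self.pools = [nn.GlobalAvgPool2d() for _ in self.blocks]
        self.dense = nn.Dense(sum(chans), spec.n_classes, rng)
        self.children = [*self.blocks, self.dense]
        self._chans = chans

    def forward(self, x, train=True):
        """Logits of shape (N, 2) for input images (N, 1, H, W)."""
        x = self.dropout.forward(x, train)
        feats = []
        for blk, pool in zip(self.blocks, self.pools):
            x = blk.forward(x, train)
            feats.append(pool.forward(x, train))
        self._split = np.cumsum([f.shape[1] for f in feats])[:-1]
        return self.dense.forward(np.concatenate(feats, axis=1), train)

    def predict_proba(self, x):
        return softmax(self.forward(x, train=False), axis=1)

    def backward(self, dlogits):
        dfeat = self.dense.backward(dlogits)
        dfeats = np.split(dfeat, self._split, axis=1)
        dx = None
        for blk, pool, df in zip(reversed(self.blocks), reversed(self.pools),
                                 reversed(dfeats)):
            g = pool.backward(df)
            if dx is not None:
                g = g + dx
            dx = blk.backward(g)
        return self.dropout.backward(dx)


class Segmenter(nn.Module):
    """Residual encoder-decoder segmentation network (V-Net style)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        super().__init__()
        if len(spec.blocks) != 6:
            raise ValueError("segmenter expects exactly 6 contracting blocks")
        stride_prod = 1
        for b in spec.blocks:
            stride_prod *= b.s1
        if spec.input_size % stride_prod != 0:
            raise ValueError(
                f"input size {spec.input_size} not divisible by the stride chain "
                f"({stride_prod})"
            )
        self.spec = spec
        rng = np.random.default_rng(seed)
        chans = spec.scaled_channels()
        self.dropout = nn.Dropout(spec.dropout_rate)
        self.down = []
        cin = 1
        for b, c in zip(spec.blocks, chans):
            self.down.append(_RBl(cin, c, b.k1, b.s1, rng))
            cin = c
        # expanding path: mirror strides/kernels; channels halve per level,
        # each level concatenates the same-resolution contracting features
        self.up = []
        up_src = chans[-1]
        for lvl in range(5, 0, -1):
            b = spec.blocks[lvl]
            self.up.append(_RBr(up_src, chans[lvl - 1], chans[lvl - 1], b.k1, b.s1, rng))
            up_src = chans[lvl - 1]
        # final stride-1 expanding block mirrors block 1 (no skip remains)
        self.up.append(_RBl(chans[0], chans[0], 1, 1, rng))
        self.head = nn.Conv2d(chans[0], spec.n_classes, 1, 1, rng)
        self.children = [*self.down, *self.up, self.head]

    def forward(self, x, train=True):
        """Logits of shape (N, n_classes, H, W)."""
        x = self.dropout.forward(x, train)
        skips = []
        for blk in self.down:
            x = blk.forward(x, train)
            skips.append(x)
        for i, blk in enumerate(self.up[:-1]):
            x = blk.forward(x, skips[4 - i], train)
        x = self.up[-1].forward(x, train)
        return self.head.forward(x, train)

    def predict_proba(self, x):
        """Per-pixel class probabilities, shape (N, n_classes, H, W)."""
        return softmax(self.forward(x, train=False), axis=1)

    def predict_labels(self, x):
        return np.argmax(self.forward(x, train=False), axis=1)

    def backward(self, dlogits):
        g = self.head.backward(dlogits)
        g = self.up[-1].backward(g)
        gskips = [None] * 6
        for i in range(4, -1, -1):
            g, gs = self.up[i].backward(g)
            gskips[4 - i] = gs
        # g is now the gradient into skips[5] (deepest); add stored skip grads
        for lvl in range(5, -1, -1):
            if gskips[lvl] is not None:
                g = g + gskips[lvl]
            g = self.down[lvl].backward(g)
        return self.dropout.backward(g)


def build_classifier(spec: NetworkSpec, seed: int = 0, activation="relu") -> Classifier:
    return Classifier(spec, seed=seed, activation=activation)


def build_segmenter(spec: NetworkSpec, seed: int = 0) -> Segmenter:
    return Segmenter(spec, seed=seed)
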