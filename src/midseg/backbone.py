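"""Reduced ResNet50 feature extractor.

The encoder backbone is ResNet50 with its fifth convolution stage removed:
stem (7x7/2 conv + 3x3/2 max-pool) followed by the bottleneck stages
conv2 (3 blocks), conv3 (4 blocks) and conv4 (6 blocks).  Three internal
activations are exported as the feature pyramid:

===========  ======  ========  ===============================
tap          stride  channels  position
===========  ======  ========  ===============================
``low``      4       64        after the 3x3 conv (+BN+ReLU) of the last
                               conv2 bottleneck
``middle``   8       128       same position in the last conv3 bottleneck
``deep``     16      256       same position in the last conv4 bottleneck
===========  ======  ========  ===============================

Because the deep tap sits *inside* the last conv4 bottleneck, the final
1x1 expansion conv of that block (and the residual add) contributes
nothing downstream and is not built — exactly the sub-graph a functional
model with these three outputs retains.  Convolutions carry biases,
following the canonical ResNet50 weight layout.

Input preprocessing is pinned to: scale to [0, 1], then per-channel
standardization with the ImageNet statistics (mean 0.485/0.456/0.406,
std 0.229/0.224/0.225).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine as eng
from ._engine import Conv2D, BatchNorm, Module, Tensor

__all__ = ["FeaturePyramid", "Bottleneck", "ReducedResNet50",
           "build_reduced_resnet50", "preprocess_images", "IMAGENET_MEAN", "IMAGENET_STD"]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

OUTPUT_STRIDE = 16


@dataclass
class FeaturePyramid:
    """The three tapped backbone maps with their strides (NHWC tensors)."""

    low: Tensor  # stride 4, 64 channels
    middle: Tensor  # stride 8, 128 channels
    deep: Tensor  # stride 16, 256 channels

    strides = (4, 8, 16)
    channels = (64, 128, 256)

    def as_tuple(self):
        return (self.low, self.middle, self.deep)


def preprocess_images(images):
    """uint8/float RGB batch (N, H, W, 3) -> standardized float32 batch."""
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    arr = arr.astype(np.float32)
    if arr.max() > 1.5:  # 0..255 input
        arr = arr / 255.0
    return (arr - IMAGENET_MEAN) / IMAGENET_STD


def _check_batch(data):
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected an (N, H, W, 3) batch, got shape {data.shape}")
    n, h, w, _ = data.shape
    if n < 1:
        raise ValueError("batch must contain at least one image")
    if h % OUTPUT_STRIDE or w % OUTPUT_STRIDE:
        raise ValueError(
            f"spatial dims must be divisible by the output stride "
            f"({OUTPUT_STRIDE}); got {h}x{w}"
        )


class Bottleneck(Module):
    """ResNet v1 bottleneck: 1x1 -> 3x3 -> 1x1 with a residual connection.

    When ``truncate_after_conv2`` is set, the block ends at the ReLU after
    the 3x3 conv (the deep tap) and builds no expansion conv or shortcut.
    """

    def __init__(self, cin, width, rng, stride=1, conv_shortcut=False,
                 truncate_after_conv2=False):
        super().__init__()
        cout = 4 * width
        self.truncated = truncate_after_conv2
        self.conv1 = Conv2D(cin, width, 1, rng, stride=stride, padding="valid")
        self.bn1 = BatchNorm(width)
        self.conv2 = Conv2D(width, width, 3, rng)
        self.bn2 = BatchNorm(width)
        if not truncate_after_conv2:
            self.conv3 = Conv2D(width, cout, 1, rng, padding="valid")
            self.bn3 = BatchNorm(cout)
            if conv_shortcut:
                self.short = Conv2D(cin, cout, 1, rng, stride=stride, padding="valid")
                self.short_bn = BatchNorm(cout)
            else:
                self.short = None

    @staticmethod
    def _cba(x, conv, bn, act="relu"):
        return eng.conv_bn_act(
            x, conv.w, bn.gamma, bn.beta, bn.moving_mean, bn.moving_var,
            bn.training, b=conv.b, stride=conv.stride, padding=conv.padding,
            momentum=bn.momentum, eps=bn.eps, act=act,
        )

    def __call__(self, x):
        y = self._cba(x, self.conv1, self.bn1)
        inner = self._cba(y, self.conv2, self.bn2)  # the "_2_relu" tap activation
        if self.truncated:
            return inner, inner
        y = self._cba(inner, self.conv3, self.bn3, act=None)
        if self.short is not None:
            sc = self._cba(x, self.short, self.short_bn, act=None)
        else:
            sc = x
        return eng.add_relu(y, sc), inner


class ReducedResNet50(Module):
    """ResNet50 stages conv1-conv4 with the three pyramid taps exported."""

    def __init__(self, rng=None, seed=0):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(seed)
        self.stem_conv = Conv2D(3, 64, 7, rng, stride=2, padding=((3, 3), (3, 3)))
        self.stem_bn = BatchNorm(64)
        # (n_blocks, width, first-block stride)
        stage_specs = [(3, 64, 1), (4, 128, 2), (6, 256, 2)]
        cin = 64
        self.stages = []
        for si, (nb, width, stride) in enumerate(stage_specs):
            blocks = []
            for bi in range(nb):
                last_stage = si == len(stage_specs) - 1
                trunc = last_stage and bi == nb - 1
                blk = Bottleneck(
                    cin,
                    width,
                    rng,
                    stride=stride if bi == 0 else 1,
                    conv_shortcut=bi == 0,
                    truncate_after_conv2=trunc,
                )
                setattr(self, f"stage{si + 2}_block{bi + 1}", blk)
                blocks.append(blk)
                cin = 4 * width
            self.stages.append(blocks)

    def __call__(self, x):
        """Run the backbone; ``x`` is a Tensor or preprocessed ndarray."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        _check_batch(x.data)
        y = Bottleneck._cba(x, self.stem_conv, self.stem_bn)
        y = eng.max_pool2d(y, pool=3, stride=2, padding=((1, 1), (1, 1)))
        taps = []
        for blocks in self.stages:
            inner = None
            for blk in blocks:
                y, inner = blk(y)
            taps.append(inner)
        return FeaturePyramid(low=taps[0], middle=taps[1], deep=taps[2])

    # spec-facing alias
    def extract_features(self, images):
        """Preprocess raw images and return the feature pyramid."""
        return self(Tensor(preprocess_images(images)))


def build_reduced_resnet50(config=None, seed=0):
    """Build the reduced backbone; rejects unsupported output strides."""
    if config is not None:
        os_ = getattr(config, "output_stride", OUTPUT_STRIDE)
        if os_ != OUTPUT_STRIDE:
            raise ValueError(f"unsupported output stride {os_}; only {OUTPUT_STRIDE}")
        seed = getattr(config, "seed", seed)
    return ReducedResNet50(seed=seed)
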