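"""mid-DeepLabv3+: encoder (ASPP) + decoder with a middle-layer branch.

The network composes:

1. the reduced ResNet50 backbone (``midseg.backbone``), whose three taps
   (stride 4/8/16, 64/128/256 channels) optionally pass through SimAM;
2. an Atrous Spatial Pyramid Pooling encoder on the deep tap: a 1x1 conv,
   three 3x3 atrous *separable* convolutions at rates 6/12/18, and an
   image-pooling branch, concatenated and projected to 256 channels;
3. a decoder that reduces the low tap (1x1 -> 48 ch) and — the middle-layer
   branch — the middle tap (1x1 -> 48 ch, bilinear x2), concatenates them
   with the x4-upsampled encoder output at stride 4, refines with two 3x3
   convolutions (256 filters), upsamples x4 to full resolution and applies
   a 1x1 classifier with ``num_classes`` filters.

Bias conventions are pinned for exact parameter accounting: backbone
convolutions carry biases (canonical ResNet50 layout); head convolutions
followed by batch norm are bias-free, except the ASPP image-pooling conv;
the final classifier carries a bias.  Bilinear resizing uses the
half-pixel-center (align_corners=False) convention throughout.

The two ablation switches of the design study are exposed directly:
``attention`` ('none'/'simam', zero parameter cost either way) and
``use_mid_layer`` (the middle decoder branch, a strictly positive
parameter cost), spanning the baseline / +SimAM / +Mid-Layer / +both
configuration lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import _engine as eng
from ._engine import Conv2D, DepthwiseConv2D, BatchNorm, Module, Tensor
from .attention import ATTENTION_KINDS, DEFAULT_LAMBDA, attach_attention
from .backbone import ReducedResNet50, preprocess_images

__all__ = ["NetworkConfig", "SepConvBlock", "ConvBlock", "ASPP", "Decoder",
           "MidDeepLabV3Plus", "build_model", "count_parameters", "estimate_flops"]


@dataclass
class NetworkConfig:
    """Every architectural hyperparameter of the model."""

    num_classes: int = 11  # 10 food classes + background
    input_size: tuple = (512, 512)
    output_stride: int = 16
    aspp_rates: tuple = (6, 12, 18)
    aspp_filters: int = 256
    decoder_reduction_channels: int = 48
    decoder_refinement: str = "dense2"  # 'dense2' (reference) or 'sep1'
    attention: str = "simam"
    simam_lambda: float = DEFAULT_LAMBDA
    use_mid_layer: bool = True
    seed: int = 0

    def validate(self):
        if self.output_stride != 16:
            raise ValueError(f"unsupported output stride {self.output_stride}; only 16")
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2 (class + background)")
        if any(r < 1 for r in self.aspp_rates):
            raise ValueError(f"ASPP rates must be >= 1, got {self.aspp_rates}")
        if self.attention not in ATTENTION_KINDS:
            raise ValueError(
                f"unknown attention kind {self.attention!r}; expected one of {ATTENTION_KINDS}"
            )
        if self.decoder_refinement not in ("dense2", "sep1"):
            raise ValueError(f"unknown decoder refinement {self.decoder_refinement!r}")
        if self.simam_lambda <= 0:
            raise ValueError("simam_lambda must be positive")
        return self

    def to_dict(self):
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        d["aspp_rates"] = list(self.aspp_rates)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "input_size" in d:
            d["input_size"] = tuple(d["input_size"])
        if "aspp_rates" in d:
            d["aspp_rates"] = tuple(d["aspp_rates"])
        return cls(**d).validate()


class SepConvBlock(Module):
    """Atrous separable convolution: depthwise 3x3 (dilated) -> pointwise
    1x1 -> batch normalization -> ReLU.  No biases (BN follows)."""

    def __init__(self, cin, cout, rng, rate=1):
        super().__init__()
        if rate < 1:
            raise ValueError(f"dilation rate must be >= 1, got {rate}")
        self.dw = DepthwiseConv2D(cin, 3, rng, dilation=rate)
        self.pw = Conv2D(cin, cout, 1, rng, use_bias=False, padding="valid")
        self.bn = BatchNorm(cout)

    def __call__(self, x):
        y = self.dw(x)
        return eng.conv_bn_act(
            y, self.pw.w, self.bn.gamma, self.bn.beta, self.bn.moving_mean,
            self.bn.moving_var, self.bn.training, padding="valid",
            momentum=self.bn.momentum, eps=self.bn.eps,
        )


class ConvBlock(Module):
    """Conv -> BN -> ReLU; bias-free unless requested (pooling branch)."""

    def __init__(self, cin, cout, k, rng, rate=1, use_bias=False):
        super().__init__()
        self.conv = Conv2D(cin, cout, k, rng, dilation=rate, use_bias=use_bias,
                           padding="same" if k > 1 else "valid")
        self.bn = BatchNorm(cout)

    def __call__(self, x):
        return eng.conv_bn_act(
            x, self.conv.w, self.bn.gamma, self.bn.beta, self.bn.moving_mean,
            self.bn.moving_var, self.bn.training, b=self.conv.b,
            dilation=self.conv.dilation, padding=self.conv.padding,
            momentum=self.bn.momentum, eps=self.bn.eps,
        )


class ASPP(Module):
    """Atrous spatial pyramid pooling over the (attended) deep tap.

    Five branches — 1x1 conv, three separable atrous convs, image-level
    average pooling — concatenated and projected by a 1x1 conv.
    """

    def __init__(self, cin, config, rng):
        super().__init__()
        f = config.aspp_filters
        self.branch1 = ConvBlock(cin, f, 1, rng)
        self.atrous = []
        for i, r in enumerate(config.aspp_rates):
            blk = SepConvBlock(cin, f, rng, rate=r)
            setattr(self, f"atrous{i + 1}", blk)
            self.atrous.append(blk)
        self.pool_conv = ConvBlock(cin, f, 1, rng, use_bias=True)
        self.project = ConvBlock((2 + len(self.atrous)) * f, f, 1, rng)

    def __call__(self, deep):
        h, w = deep.shape[1], deep.shape[2]
        pooled = eng.reduce_mean(deep, axis=(1, 2), keepdims=True)
        pooled = eng.resize_bilinear(self.pool_conv(pooled), h, w)
        branches = [self.branch1(deep)] + [b(deep) for b in self.atrous] + [pooled]
        return self.project(eng.concat(branches, axis=-1))


class Decoder(Module):
    """Skip-connection decoder with the optional middle-layer branch."""

    def __init__(self, config, rng, low_ch=64, mid_ch=128):
        super().__init__()
        red = config.decoder_reduction_channels
        f = config.aspp_filters
        self.use_mid = config.use_mid_layer
        self.low_reduce = ConvBlock(low_ch, red, 1, rng)
        cat = red + f
        if self.use_mid:
            self.mid_reduce = ConvBlock(mid_ch, red, 1, rng)
            cat += red
        if config.decoder_refinement == "dense2":
            self.refine1 = ConvBlock(cat, f, 3, rng)
            self.refine2 = ConvBlock(f, f, 3, rng)
            self.refines = [self.refine1, self.refine2]
        else:  # 'sep1': a single 3x3 separable refinement
            self.refine1 = SepConvBlock(cat, f, rng)
            self.refines = [self.refine1]
        self.classifier = Conv2D(f, config.num_classes, 1, rng, use_bias=True,
                                 padding="valid")

    def __call__(self, low, middle, encoder_out):
        h4, w4 = low.shape[1], low.shape[2]
        if middle is not None and (middle.shape[1] != h4 // 2 or encoder_out.shape[1] != h4 // 4):
            raise ValueError(
                "stride mismatch: decoder expects taps at strides (4, 8, 16); got "
                f"low {low.shape[1:3]}, middle {middle.shape[1:3]}, "
                f"encoder {encoder_out.shape[1:3]}"
            )
        parts = [eng.resize_bilinear(encoder_out, h4, w4), self.low_reduce(low)]
        if self.use_mid:
            if middle is None:
                raise ValueError("mid-layer branch enabled but no middle tap given")
            parts.append(eng.resize_bilinear(self.mid_reduce(middle), h4, w4))
        y = eng.concat(parts, axis=-1)
        for blk in self.refines:
            y = blk(y)
        # The 1x1 classifier and the bilinear x4 upsample are both linear,
        # so they commute exactly; classifying first moves the upsample to
        # num_classes channels instead of aspp_filters and is much cheaper.
        y = self.classifier(y)
        return eng.resize_bilinear(y, 4 * h4, 4 * w4)


class MidDeepLabV3Plus(Module):
    """The assembled segmentation network (emits logits, softmax at use)."""

    def __init__(self, config=None):
        super().__init__()
        self.config = (config or NetworkConfig()).validate()
        rng = np.random.default_rng(self.config.seed)
        self.backbone = ReducedResNet50(rng=rng)
        self.aspp = ASPP(256, self.config, rng)
        self.decoder = Decoder(self.config, rng)

    def __call__(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        pyr = self.backbone(x)
        pyr = attach_attention(pyr, self.config.attention, self.config.simam_lambda)
        enc = self.aspp(pyr.deep)
        middle = pyr.middle if self.config.use_mid_layer else None
        return self.decoder(pyr.low, middle, enc)

    # -- inference ----------------------------------------------------------
    def predict(self, images):
        """Raw images -> integer label mask(s) via argmax (ties -> lowest id)."""
        batch = preprocess_images(images)
        with eng.no_grad():
            logits = self(Tensor(batch))
        return np.argmax(logits.data, axis=-1).astype(np.int32)

    def logits(self, images):
        batch = preprocess_images(images)
        with eng.no_grad():
            return self(Tensor(batch)).data

    # -- accounting ---------------------------------------------------------
    def parameter_table(self):
        """Per-weight listing: (name, shape, size, trainable)."""
        return [
            (name, tuple(p.data.shape), p.data.size, p.trainable)
            for name, p in self.named_parameters()
        ]

    def summary(self):
        total, tr, nt = self.count_parameters()
        lines = [f"{'weight':60s} {'shape':>20s} {'size':>12s}"]
        for name, shape, size, trainable in self.parameter_table():
            tag = "" if trainable else "  (stats)"
            lines.append(f"{name:60s} {str(shape):>20s} {size:>12,d}{tag}")
        lines.append("-" * 94)
        lines.append(f"Total params:         {total:,d}")
        lines.append(f"Trainable params:     {tr:,d}")
        lines.append(f"Non-trainable params: {nt:,d}")
        return "\n".join(lines)

    # -- checkpointing ------------------------------------------------------
    def save(self, path):
        import json

        state = {k: v for k, v in self.state_dict().items()}
        state["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **state)

    @classmethod
    def load(cls, path):
        import json

        with np.load(path) as data:
            cfg = NetworkConfig.from_dict(
                json.loads(bytes(data["__config__"].tobytes()).decode())
            )
            model = cls(cfg)
            model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model


def build_model(config=None):
    """Construct mid-DeepLabv3+ from a NetworkConfig."""
    return MidDeepLabV3Plus(config)


def count_parameters(model):
    """Exact total weight-element count (trainable + BN statistics)."""
    total, _, _ = model.count_parameters()
    return total


def _conv_flops(k, cin, cout, h, w):
    return k * k * cin * cout * h * w


def estimate_flops(model, input_size=None):
    """Analytic multiply-add count of one forward pass (MACs).

    Convention: one multiply-accumulate = 1 FLOP; batch norm, activations,
    pooling and bilinear resizing are ignored.  The figure is an estimate
    for relative comparison only.
    """
    cfg = model.config
    h, w = input_size or cfg.input_size
    total = 0
    # backbone
    h2, w2 = h // 2, w // 2
    total += _conv_flops(7, 3, 64, h2, w2)
    hs, ws = h // 4, w // 4
    cin = 64
    for nb, width, stride in [(3, 64, 1), (4, 128, 2), (6, 256, 2)]:
        if stride == 2:
            hs, ws = hs // 2, ws // 2
        cout = 4 * width
        for bi in range(nb):
            last = (width == 256 and bi == nb - 1)
            c0 = cin if bi == 0 else cout
            total += _conv_flops(1, c0, width, hs, ws)
            total += _conv_flops(3, width, width, hs, ws)
            if not last:
                total += _conv_flops(1, width, cout, hs, ws)
            if bi == 0:
                total += _conv_flops(1, cin, cout, hs, ws)
        cin = cout
    # ASPP on stride-16 map
    h16, w16 = h // 16, w // 16
    f = cfg.aspp_filters
    total += _conv_flops(1, 256, f, h16, w16)
    for _ in cfg.aspp_rates:
        total += 9 * 256 * h16 * w16 + _conv_flops(1, 256, f, h16, w16)
    total += 1 * 256 * f  # pooling-branch 1x1 on the pooled pixel
    total += _conv_flops(1, 5 * f, f, h16, w16)
    # decoder at stride 4
    h4, w4 = h // 4, w // 4
    red = cfg.decoder_reduction_channels
    total += _conv_flops(1, 64, red, h4, w4)
    cat = red + f
    if cfg.use_mid_layer:
        total += _conv_flops(1, 128, red, h // 8, w // 8)
        cat += red
    if cfg.decoder_refinement == "dense2":
        total += _conv_flops(3, cat, f, h4, w4) + _conv_flops(3, f, f, h4, w4)
    else:
        total += 9 * cat * h4 * w4 + _conv_flops(1, cat, f, h4, w4)
    total += _conv_flops(1, f, cfg.num_classes, h, w)
    return float(total)
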