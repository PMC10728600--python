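"""DCSAnet: encoder (stem + three DCA stages), guided-aggregation decoder,
and the analytic model summary.

Encoder layout::

    stem 3x3/2 -> stage1 [DCA-B, DCA-A]            -> feat1  (1/4  scale)
              -> stage2 [DCA-B, DCA-A]             -> feat2  (1/8  scale)
              -> stage3 [DCA-B, 3x DCA-A,
                         DCA-B, 3x DCA-A + SE]     -> feat3  (1/32 scale)

Each DCA-B doubles the width, so the stage widths follow the stem width
``s`` as ``2s, 4s, 16s``.  The decoder upsamples feat3 in steps, fusing
feat2 and feat1 U-Net style (concatenation followed by a 3x3 convolution)
and refining at 1/2 and full resolution before a 1x1 classifier.  The
guided variants modulate feat1 with a transform of a deeper map (feat2 or
feat3) by elementwise multiplication before the fusion; the residual
variants add the unmodulated feat1 back.

Default widths were fixed by the calibration procedure in
``scripts/calibrate_widths.py`` so that the parameter count and the analytic
FLOPs of the plain-decoder and full models land on the published values
(0.45 M / 17.00 G and 0.57 M / 18.06 G at 512x512).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Var
from .blocks import DCABlock, DCABlockConfig, count_params
from .layers import (
    BatchNorm2d,
    BilinearUpsample,
    Conv2d,
    Module,
    ReLU,
    Sequential,
)

__all__ = [
    "ModelConfig",
    "EncoderFeatures",
    "CostReport",
    "DCSANet",
    "build_model",
    "model_summary",
    "guided_aggregation",
    "DECODER_VARIANTS",
    "save_checkpoint",
    "load_checkpoint",
]

DECODER_VARIANTS = (
    "plain",
    "feat2_guided",
    "feat3_guided",
    "feat2_guided_residual",
    "feat3_guided_residual",
)


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture description.

    ``stage_widths`` are the output widths of the three encoder stages and
    must follow the doubling rule implied by the DCA-B blocks
    (``2*stem, 4*stem, 16*stem``).  ``kernel_N`` is the large branch kernel
    (the ablation knob); the other branch uses ``kernel_small``.
    """

    stem_channels: int = 5
    stage_widths: tuple = (10, 20, 80)
    kernel_N: int = 7
    kernel_small: int = 3
    use_shuffle: bool = True
    use_attention: bool = True
    attention_on_expanded: bool = False
    decoder_variant: str = "feat3_guided_residual"
    decoder_widths: tuple = (24, 96, 132, 28)
    guide_widths: tuple = (96, 58)
    num_classes: int = 4
    input_divisor: int = 32

    def __post_init__(self):
        if self.decoder_variant not in DECODER_VARIANTS:
            raise ValueError(
                f"unknown decoder variant {self.decoder_variant!r}; expected one of {DECODER_VARIANTS}"
            )
        s = self.stem_channels
        expected = (2 * s, 4 * s, 16 * s)
        if tuple(self.stage_widths) != expected:
            raise ValueError(
                f"stage widths {self.stage_widths} inconsistent with stem {s}; "
                f"each DCA-B doubles the width, so they must be {expected}"
            )
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.kernel_N % 2 == 0 or self.kernel_small % 2 == 0:
            raise ValueError("branch kernels must be odd")
        if len(self.decoder_widths) != 4:
            raise ValueError("decoder_widths must have 4 entries (1/8, 1/4, 1/2, full)")
        if len(self.guide_widths) != 2:
            raise ValueError("guide_widths must have 2 entries")

    @classmethod
    def paper(cls, decoder_variant="feat3_guided_residual", kernel_N=7, use_shuffle=True,
              num_classes=4):
        """The calibrated full-size configuration."""
        return cls(decoder_variant=decoder_variant, kernel_N=kernel_N,
                   use_shuffle=use_shuffle, num_classes=num_classes)

    @classmethod
    def tiny(cls, decoder_variant="feat3_guided_residual", num_classes=4):
        """The smallest usable configuration; for fast unit tests."""
        return cls(
            stem_channels=4,
            stage_widths=(8, 16, 64),
            decoder_widths=(16, 16, 16, 12),
            guide_widths=(12, 8),
            decoder_variant=decoder_variant,
            num_classes=num_classes,
        )

    @classmethod
    def small(cls, decoder_variant="feat3_guided_residual", num_classes=4):
        """A reduced-width configuration for CPU experiments (the synthetic
        learnability study trains this on 128x128 scenes)."""
        return cls(
            stem_channels=8,
            stage_widths=(16, 32, 128),
            decoder_widths=(32, 48, 48, 32),
            guide_widths=(24, 16),
            decoder_variant=decoder_variant,
            num_classes=num_classes,
        )

    def to_json(self):
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text):
        payload = json.loads(text)
        for key in ("stage_widths", "decoder_widths", "guide_widths"):
            payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class EncoderFeatures:
    """The three encoder outputs at 1/4, 1/8 and 1/32 of the input."""

    feat1: Var
    feat2: Var
    feat3: Var


@dataclass(frozen=True)
class CostReport:
    """Model size at a stated input resolution."""

    params_millions: float
    flops_billions: float
    input_size: int

    def to_json(self):
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# encoder


class Encoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        s = cfg.stem_channels
        kw = dict(
            kernel_small=cfg.kernel_small,
            kernel_large=cfg.kernel_N,
            use_shuffle=cfg.use_shuffle,
            attention_on_expanded=cfg.attention_on_expanded,
        )
        self.stem = Sequential(Conv2d(3, s, 3, stride=2, rng=rng), BatchNorm2d(s), ReLU())
        self.stage1 = Sequential(
            DCABlock(DCABlockConfig(s, "B", **kw), rng=rng),
            DCABlock(DCABlockConfig(2 * s, "A", **kw), rng=rng),
        )
        self.stage2 = Sequential(
            DCABlock(DCABlockConfig(2 * s, "B", **kw), rng=rng),
            DCABlock(DCABlockConfig(4 * s, "A", **kw), rng=rng),
        )
        deep = [DCABlock(DCABlockConfig(4 * s, "B", **kw), rng=rng)]
        deep += [DCABlock(DCABlockConfig(8 * s, "A", **kw), rng=rng) for _ in range(3)]
        deep += [DCABlock(DCABlockConfig(8 * s, "B", **kw), rng=rng)]
        deep += [
            DCABlock(DCABlockConfig(16 * s, "A", use_attention=cfg.use_attention, **kw), rng=rng)
            for _ in range(3)
        ]
        self.stage3 = Sequential(*deep)

    def forward(self, x):
        x = self.stem(x)
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        return EncoderFeatures(feat1=f1, feat2=f2, feat3=f3)

    def macs(self, shape):
        total = self.stem.macs(shape)
        shape = self.stem.out_shape(shape)
        for stage in (self.stage1, self.stage2, self.stage3):
            total += stage.macs(shape)
            shape = stage.out_shape(shape)
        return total


# ---------------------------------------------------------------------------
# guided aggregation


class GuidedAggregation(Module):
    """Use a deep, semantically rich map to modulate a shallow, detailed one.

    The guide is brought to 1/8 scale, filtered by a 3x3 convolution, brought
    to the target's scale, filtered again, and projected to the target width;
    the result multiplies the target elementwise.  With ``residual`` the
    original target is added back.
    """

    def __init__(self, guide_channels, target_channels, guide_widths, guide_scale_to_eighth,
                 residual, rng):
        super().__init__()
        g1, g2 = guide_widths
        self.residual = residual
        self.pre_scale = guide_scale_to_eighth  # 4 for feat3 (1/32 -> 1/8), 1 for feat2
        self.conv1 = Conv2d(guide_channels, g1, 3, rng=rng)
        self.bn1 = BatchNorm2d(g1)
        self.conv2 = Conv2d(g1, g2, 3, rng=rng)
        self.bn2 = BatchNorm2d(g2)
        self.gate = Conv2d(g2, target_channels, 1, bias=True, rng=rng)

    def forward(self, target: Var, guide: Var) -> Var:
        th, tw = target.shape[2], target.shape[3]
        g = guide
        if self.pre_scale != 1:
            g = ag.bilinear_resize(g, (g.shape[2] * self.pre_scale, g.shape[3] * self.pre_scale))
        g = ag.relu(self.bn1(self.conv1(g)))
        g = ag.bilinear_resize(g, (th, tw))
        g = ag.relu(self.bn2(self.conv2(g)))
        g = self.gate(g)
        out = ag.mul(target, g)
        if self.residual:
            out = ag.add(out, target)
        return out

    def macs(self, guide_shape, target_shape):
        gc, gh, gw = guide_shape
        tc, th, tw = target_shape
        h8, w8 = gh * self.pre_scale, gw * self.pre_scale
        total = self.conv1.macs((gc, h8, w8))
        total += self.conv2.macs((self.conv1.out_channels, th, tw))
        total += self.gate.macs((self.conv2.out_channels, th, tw))
        return total


def guided_aggregation(target: Var, guide: Var, residual: bool, guide_widths=(96, 58), rng=None):
    """Functional form over freshly initialised weights (mainly for tests)."""
    rng = rng or np.random.default_rng(0)
    scale = target.shape[2] * 2 // guide.shape[2] if guide.shape[2] * 2 < target.shape[2] else 1
    mod = GuidedAggregation(guide.shape[1], target.shape[1], guide_widths, scale, residual, rng)
    return mod(target, guide)


# ---------------------------------------------------------------------------
# decoder + full model


class Decoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        s = cfg.stem_channels
        c1, c2, c3 = 2 * s, 4 * s, 16 * s
        d1, d2, d3, d4 = cfg.decoder_widths
        k = cfg.num_classes
        self.variant = cfg.decoder_variant
        self.up_feat3 = BilinearUpsample(4)
        self.fuse2 = Sequential(Conv2d(c3 + c2, d1, 3, rng=rng), BatchNorm2d(d1), ReLU())
        self.up2 = BilinearUpsample(2)
        if self.variant != "plain":
            guide_c = c2 if "feat2" in self.variant else c3
            pre_scale = 1 if "feat2" in self.variant else 4
            self.guide = GuidedAggregation(
                guide_c, c1, cfg.guide_widths, pre_scale,
                residual=self.variant.endswith("residual"), rng=rng,
            )
        else:
            self.guide = None
        self.fuse1 = Sequential(Conv2d(d1 + c1, d2, 3, rng=rng), BatchNorm2d(d2), ReLU())
        self.up1 = BilinearUpsample(2)
        self.refine_half = Sequential(Conv2d(d2, d3, 3, rng=rng), BatchNorm2d(d3), ReLU())
        self.up0 = BilinearUpsample(2)
        self.refine_full = Sequential(Conv2d(d3, d4, 3, rng=rng), BatchNorm2d(d4), ReLU())
        self.classifier = Conv2d(d4, k, 1, bias=True, rng=rng)
        self._chans = (c1, c2, c3)

    def forward(self, feats: EncoderFeatures) -> Var:
        x = self.up_feat3(feats.feat3)
        x = self.fuse2(ag.concat([x, feats.feat2], axis=1))
        x = self.up2(x)
        f1 = feats.feat1
        if self.guide is not None:
            guide = feats.feat2 if "feat2" in self.variant else feats.feat3
            f1 = self.guide(f1, guide)
        x = self.fuse1(ag.concat([x, f1], axis=1))
        x = self.refine_half(self.up1(x))
        x = self.refine_full(self.up0(x))
        return self.classifier(x)

    def macs(self, input_hw):
        h, w = input_hw
        c1, c2, c3 = self._chans
        r8, r4, r2, r1 = (h // 8, w // 8), (h // 4, w // 4), (h // 2, w // 2), (h, w)
        total = self.fuse2.macs((c3 + c2, *r8))
        if self.guide is not None:
            guide_shape = (c2, *r8) if "feat2" in self.variant else (c3, h // 32, w // 32)
            total += self.guide.macs(guide_shape, (c1, *r4))
        d1 = self.fuse2.layers[0].out_channels
        total += self.fuse1.macs((d1 + c1, *r4))
        d2 = self.fuse1.layers[0].out_channels
        total += self.refine_half.macs((d2, *r2))
        d3 = self.refine_half.layers[0].out_channels
        total += self.refine_full.macs((d3, *r1))
        d4 = self.refine_full.layers[0].out_channels
        total += self.classifier.macs((d4, *r1))
        return total


class DCSANet(Module):
    """The full segmentation model: encoder, decoder, classifier head."""

    def __init__(self, cfg: ModelConfig, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)

    def _check_input(self, x):
        if x.shape[1] != 3:
            raise ValueError(f"expected 3-channel RGB input, got {x.shape[1]} channels")
        d = self.cfg.input_divisor
        if x.shape[2] % d or x.shape[3] % d:
            raise ValueError(
                f"input spatial dims {x.shape[2]}x{x.shape[3]} must be divisible by {d}"
            )

    def forward_encoder(self, x) -> EncoderFeatures:
        if not isinstance(x, Var):
            x = Var(x)
        self._check_input(x)
        return self.encoder(x)

    def forward(self, x) -> Var:
        feats = self.forward_encoder(x)
        return self.decoder(feats)

    def predict(self, x) -> np.ndarray:
        """Label mask (N, H, W) from an image batch, in eval mode."""
        was_training = self.training
        self.eval()
        try:
            logits = self.forward(x)
        finally:
            self.train(was_training)
        return logits.data.argmax(axis=1)

    def macs(self, input_size):
        h = w = input_size
        return self.encoder.macs((3, h, w)) + self.decoder.macs((h, w))


def build_model(cfg: ModelConfig, seed=0) -> DCSANet:
    return DCSANet(cfg, seed=seed)


def model_summary(model: DCSANet, input_size=512) -> CostReport:
    """Parameter count and analytic FLOPs at a square input resolution.

    Convention: one FLOP per multiply-accumulate; convolution and linear
    layers only.
    """
    if input_size % model.cfg.input_divisor:
        raise ValueError(f"input_size must be divisible by {model.cfg.input_divisor}")
    return CostReport(
        params_millions=count_params(model) / 1e6,
        flops_billions=model.macs(input_size) / 1e9,
        input_size=input_size,
    )


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: DCSANet, path):
    """Write weights (.npz) plus a JSON sidecar with the ModelConfig."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **model.state_dict())
    sidecar = (path[:-4] if path.endswith(".npz") else path) + ".json"
    with open(sidecar, "w") as fh:
        fh.write(model.cfg.to_json())


def load_checkpoint(path) -> DCSANet:
    path = str(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    sidecar = path[:-4] + ".json"
    with open(sidecar) as fh:
        cfg = ModelConfig.from_json(fh.read())
    model = DCSANet(cfg)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
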