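"""Image pathway: truncated MobileNetV2-style backbone, the multi-scale
dilated fusion attention block (MDFA), and pooling to the 256-d image
embedding F_img.

The backbone is the standard inverted-residual stack (expand 1x1 -> depthwise
3x3 -> project 1x1, ReLU6, residual when shapes match) truncated before the
final 1280-channel expansion, so its last stage emits 320 channels at 1/32 of
the input resolution (448 px in -> 14x14 out).  A width multiplier and a
repeats flag produce slim variants for scaled-down training.

MDFA runs three parallel views of that map -- a local-detail branch (3x3
conv, dilation 6, 13x13 receptive field), a global-trend branch (3x3 conv,
dilation 12, 25x25 receptive field) and a spatially-constant global-context
branch (GAP -> 1x1 conv -> broadcast) -- concatenates them, fuses with a 1x1
conv to 256 channels, and modulates the fused map with a sigmoid spatial
attention gate produced by a dedicated 1x1 conv.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Tensor

__all__ = [
    "receptive_field", "BackboneConfig", "MobileNetBackbone", "MDFA",
    "ImageBranch", "image_feature_vector",
]


def receptive_field(kernel: int, dilation: int) -> int:
    """Effective receptive-field side of a dilated kernel:
    ``kernel + (kernel - 1) * (dilation - 1)``."""
    if kernel < 1 or dilation < 1:
        raise ValueError("kernel and dilation must be positive")
    return kernel + (kernel - 1) * (dilation - 1)


# ---------------------------------------------------------------------------
# Backbone
# ---------------------------------------------------------------------------

#: (expansion t, channels c, repeats n, stride s) -- the standard plan.
_INVERTED_RESIDUAL_PLAN = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
)


@dataclass(frozen=True)
class BackboneConfig:
    """Size knobs for the feature extractor.

    ``width`` scales every channel count (320 -> 80 at width 0.25);
    ``single_repeats`` collapses each stage to one block for slim test
    models.  The output stride is always 32.
    """

    width: float = 1.0
    single_repeats: bool = False

    def scaled(self, channels: int) -> int:
        return max(1, int(round(channels * self.width)))

    @property
    def out_channels(self) -> int:
        return self.scaled(320)


class _ConvBnAct(Module):
    def __init__(self, cin, cout, kernel, rng, *, stride=1, groups=1):
        super().__init__()
        pad = (kernel - 1) // 2
        self.conv = nn.Conv2d(cin, cout, kernel, rng, stride=stride,
                              padding=pad, groups=groups, bias=False)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return nn.relu6(self.bn(self.conv(x)))


class _InvertedResidual(Module):
    def __init__(self, cin, cout, stride, expand, rng):
        super().__init__()
        hidden = cin * expand
        self.use_res = stride == 1 and cin == cout
        self.expand = (_ConvBnAct(cin, hidden, 1, rng) if expand != 1 else None)
        self.depthwise = _ConvBnAct(hidden, hidden, 3, rng, stride=stride,
                                    groups=hidden)
        self.project = nn.Conv2d(hidden, cout, 1, rng, bias=False)
        self.project_bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        out = x if self.expand is None else self.expand(x)
        out = self.depthwise(out)
        out = self.project_bn(self.project(out))
        if self.use_res:
            out = nn.add(out, x)
        return out


class MobileNetBackbone(Module):
    """Inverted-residual feature extractor truncated at the 320-channel stage."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c_stem = config.scaled(32)
        self.stem = _ConvBnAct(3, c_stem, 3, rng, stride=2)
        blocks = []
        cin = c_stem
        for t, c, n, s in _INVERTED_RESIDUAL_PLAN:
            cout = config.scaled(c)
            reps = 1 if config.single_repeats else n
            for i in range(reps):
                blocks.append(_InvertedResidual(cin, cout, s if i == 0 else 1,
                                                t, rng))
                cin = cout
        self.blocks = nn.ModuleList(blocks)
        self.out_channels = cin

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 3:
            raise ValueError("backbone expects a 3-channel image batch")
        if min(x.shape[2], x.shape[3]) < 32:
            raise ValueError("backbone input side must be >= 32")
        out = self.stem(x)
        for block in self.blocks:
            out = block(out)
        return out


# ---------------------------------------------------------------------------
# MDFA
# ---------------------------------------------------------------------------

class MDFA(Module):
    """Multi-scale dilated fusion attention over a feature map.

    Branch widths follow the reference layer table: 128 channels per branch,
    384 after concatenation, 256 after the 1x1 fusion conv.  The spatial
    attention gate is a separate 1x1 conv + sigmoid on the fused map, and the
    output is the fused map modulated elementwise by the gate.
    """

    def __init__(self, in_channels: int, rng: np.random.Generator, *,
                 branch_channels: int = 128, out_channels: int = 256,
                 local_dilation: int = 6, global_dilation: int = 12):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.local_conv = nn.Conv2d(in_channels, branch_channels, 3, rng,
                                    padding=local_dilation,
                                    dilation=local_dilation, bias=False)
        self.local_bn = nn.BatchNorm2d(branch_channels)
        self.global_conv = nn.Conv2d(in_channels, branch_channels, 3, rng,
                                     padding=global_dilation,
                                     dilation=global_dilation, bias=False)
        self.global_bn = nn.BatchNorm2d(branch_channels)
        self.context_conv = nn.Conv2d(in_channels, branch_channels, 1, rng,
                                      bias=False)
        self.context_bn = nn.BatchNorm2d(branch_channels)
        self.fuse_conv = nn.Conv2d(3 * branch_channels, out_channels, 1, rng,
                                   bias=False)
        self.fuse_bn = nn.BatchNorm2d(out_channels)
        self.attn_conv = nn.Conv2d(out_channels, out_channels, 1, rng)

    def local_branch(self, x: Tensor) -> Tensor:
        """3x3 conv, dilation 6, same padding -> BN -> ReLU (local details)."""
        return nn.relu(self.local_bn(self.local_conv(x)))

    def global_branch(self, x: Tensor) -> Tensor:
        """3x3 conv, dilation 12, same padding -> BN -> ReLU (global trend)."""
        return nn.relu(self.global_bn(self.global_conv(x)))

    def context_branch(self, x: Tensor) -> Tensor:
        """GAP -> 1x1 conv -> BN -> ReLU -> broadcast back to HxW.

        Every output channel is spatially constant by construction (bilinear
        interpolation of a 1x1 map is a constant fill).
        """
        h, w = x.shape[2], x.shape[3]
        pooled = nn.tensor_mean(x, axis=(2, 3), keepdims=True)
        ctx = nn.relu(self.context_bn(self.context_conv(pooled)))
        return nn.tile_spatial(ctx, h, w)

    def fuse(self, f_local: Tensor, f_global: Tensor,
             f_context_up: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Concatenate -> 1x1 fuse -> attention gate -> modulated output.

        Returns ``(f_fused_intermediate, a_spatial, x_out)``.
        """
        if not (f_local.shape[2:] == f_global.shape[2:] == f_context_up.shape[2:]):
            raise ValueError("branch outputs must share spatial size")
        cat = nn.concat([f_local, f_global, f_context_up], axis=1)
        fused = nn.relu(self.fuse_bn(self.fuse_conv(cat)))
        a_spatial = nn.sigmoid(self.attn_conv(fused))
        x_out = nn.mul(fused, a_spatial)
        return fused, a_spatial, x_out

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"MDFA expects {self.in_channels} channels, got {x.shape[1]}")
        _, _, x_out = self.fuse(self.local_branch(x), self.global_branch(x),
                                self.context_branch(x))
        return x_out


def image_feature_vector(x_out: Tensor) -> Tensor:
    """Global average pool + flatten: (N, C, H, W) -> (N, C)."""
    pooled = nn.tensor_mean(x_out, axis=(2, 3))
    return pooled


class ImageBranch(Module):
    """Backbone + MDFA + pooling -> 256-d image embedding F_img."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator,
                 embed_dim: int = 256):
        super().__init__()
        self.backbone = MobileNetBackbone(config, rng)
        self.mdfa = MDFA(self.backbone.out_channels, rng,
                         out_channels=embed_dim)
        self.embed_dim = embed_dim
        self._last_mdfa_out: Tensor | None = None

    def forward(self, images: Tensor) -> Tensor:
        features = self.backbone(images)
        x_out = self.mdfa(features)
        self._last_mdfa_out = x_out  # kept for activation mapping
        return image_feature_vector(x_out)
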