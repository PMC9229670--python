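"""Generator and discriminator architectures.

The segmentation generator is two U-Net-shaped subnetworks run in sequence:

* subnet 1 — a plain U-Net.  Each encoder level applies a stride-2 3x3
  convolution (halving the spatial side, doubling the channel width) followed
  by a refining 3x3 convolution, each with instance normalization and
  LeakyReLU.  The decoder mirrors it with stride-2 3x3 transposed
  convolutions, concatenation skip connections from the matching encoder
  level, and a refining convolution per level.
* subnet 2 — the same topology with every refining convolution replaced by a
  residual block (two 3x3 convolutions with instance norm whose output is
  summed with the block input).  Residual blocks preserve channel count, so
  in the decoder the block sits on the transposed-conv output before the
  skip concatenation; the next transposed convolution absorbs the doubled
  width.

Both subnets end in a single-channel 3x3 convolution with tanh; subnet 2
consumes subnet 1's one-channel output.  Dropout in each bottleneck plays the
role of the GAN noise input z.  The discriminator is a PatchGAN: four
stride-2 4x4 convolutions with instance norm and LeakyReLU, dropout, then a
single-filter same-padding 4x4 convolution and a sigmoid, judging each
receptive-field patch separately (a 16x16 verdict map for 256x256 input).

Default channel widths are calibrated so the full generator carries ~65
million trainable parameters (subnet 1 alone ~30 million, i.e. the full model
is roughly twice a conventional U-Net) and the discriminator ~6.9 million.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

GENERATOR_VARIANTS = ("uur", "single_unet", "concat_unets")


@dataclass
class GeneratorConfig:
    in_channels: int = 1
    levels: int = 4
    base_filters: int = 125
    res_base_filters: int = 112
    dropout_p: float = 0.1
    negative_slope: float = 0.2
    variant: str = "uur"

    def validate(self) -> "GeneratorConfig":
        if self.levels < 1:
            raise ValueError("generator.levels must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("generator.dropout_p must be in [0, 1)")
        if self.base_filters < 1 or self.res_base_filters < 1:
            raise ValueError("generator base filter widths must be positive")
        if self.variant not in GENERATOR_VARIANTS:
            raise ValueError(f"generator.variant must be one of {GENERATOR_VARIANTS}")
        return self


@dataclass
class DiscriminatorConfig:
    in_channels: int = 2  # conditioning slice stacked with the mask
    levels: int = 4
    base_filters: int = 101
    filter_size: int = 4
    dropout_p: float = 0.1
    negative_slope: float = 0.2

    def validate(self) -> "DiscriminatorConfig":
        if self.levels < 1:
            raise ValueError("discriminator.levels must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("discriminator.dropout_p must be in [0, 1)")
        if self.base_filters < 1:
            raise ValueError("discriminator.base_filters must be positive")
        return self


@dataclass
class NetworkHandle:
    """A built network plus its config and parameter count."""

    role: str  # "generator" | "discriminator"
    config: object
    model: nn.Module
    trainable_parameter_count: int = field(init=False)

    def __post_init__(self):
        self.trainable_parameter_count = self.model.num_parameters()

    def __call__(self, x):
        return self.model(x)


def count_parameters(net) -> int:
    """Total size of all trainable weight arrays."""
    if isinstance(net, NetworkHandle):
        net = net.model
    return net.num_parameters()


def _check_side(side: int, levels: int) -> None:
    if side % (1 << levels) != 0:
        raise ValueError(f"input side {side} is not divisible by 2^{levels}")


class ResidualBlock(nn.Module):
    """y = LeakyReLU(F(x) + x) with F = IN(conv3(LReLU(IN(conv3(x))))).

    Channel count is preserved; a mismatch is a construction error by design.
    """

    def __init__(self, channels: int, rng, negative_slope: float = 0.2):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, rng)
        self.norm1 = nn.InstanceNorm2d(channels)
        self.act = nn.LeakyReLU(negative_slope)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng)
        self.norm2 = nn.InstanceNorm2d(channels)

    def forward(self, x):
        f = self.norm2(self.conv2(self.act(self.norm1(self.conv1(x)))))
        return nn.leaky_relu(nn.add(f, x), self.act.negative_slope)


class _ConvBlock(nn.Module):
    def __init__(self, in_ch, out_ch, k, rng, stride=1, slope=0.2):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, k, rng, stride=stride)
        self.norm = nn.InstanceNorm2d(out_ch)
        self.act = nn.LeakyReLU(slope)

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


class _UpBlock(nn.Module):
    def __init__(self, in_ch, out_ch, rng, slope=0.2):
        super().__init__()
        self.up = nn.ConvTranspose2d(in_ch, out_ch, 3, rng, stride=2, padding=1)
        self.norm = nn.InstanceNorm2d(out_ch)
        self.act = nn.LeakyReLU(slope)

    def forward(self, x):
        return self.act(self.norm(self.up(x)))


class UNetSubnet(nn.Module):
    """One U-Net-shaped subnet; ``residual=True`` swaps the refining
    convolutions for residual blocks (decoder blocks sit before the skip
    concatenation so channel counts are preserved)."""

    def __init__(self, in_channels, levels, base, rng, dropout_p, slope, residual):
        super().__init__()
        self.levels = levels
        self.residual = residual
        widths = [base * (1 << i) for i in range(levels)]
        self.down, self.refine_down = [], []
        c = in_channels
        for w in widths:
            self.down.append(_ConvBlock(c, w, 3, rng, stride=2, slope=slope))
            if residual:
                self.refine_down.append(ResidualBlock(w, rng, slope))
            else:
                self.refine_down.append(_ConvBlock(w, w, 3, rng, slope=slope))
            c = w
        self.bottleneck_dropout = nn.Dropout(dropout_p, rng)
        self.up, self.refine_up = [], []
        # decoder targets mirror the encoder, ending at the base width
        targets = [widths[i - 1] if i > 0 else widths[0] for i in range(levels - 1, -1, -1)]
        c = widths[-1]
        for j, w in enumerate(targets):
            self.up.append(_UpBlock(c, w, rng, slope=slope))
            if residual:
                self.refine_up.append(ResidualBlock(w, rng, slope))
                c = w + w if j + 1 < levels else w
            else:
                cat = w + w if j + 1 < levels else w
                self.refine_up.append(_ConvBlock(cat, w, 3, rng, slope=slope))
                c = w
        self.head = nn.Conv2d(targets[-1], 1, 3, rng)

    def forward(self, x):
        _check_side(x.shape[2], self.levels)
        _check_side(x.shape[3], self.levels)
        skips = []
        h = x
        for down, refine in zip(self.down, self.refine_down):
            h = refine(down(h))
            skips.append(h)
        h = self.bottleneck_dropout(h)
        for j, (up, refine) in enumerate(zip(self.up, self.refine_up)):
            skip = skips[self.levels - 2 - j] if j + 1 < self.levels else None
            if self.residual:
                h = refine(up(h))
                if skip is not None:
                    h = nn.concat([h, skip], axis=1)
            else:
                h = up(h)
                if skip is not None:
                    h = nn.concat([h, skip], axis=1)
                h = refine(h)
        return nn.tanh(self.head(h))


class DualUNetGenerator(nn.Module):
    """Plain U-Net followed by a residual U-Net; the inter-subnet link is the
    one-channel output of subnet 1."""

    def __init__(self, cfg: GeneratorConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.unet = UNetSubnet(
            cfg.in_channels, cfg.levels, cfg.base_filters, rng,
            cfg.dropout_p, cfg.negative_slope, residual=False,
        )
        self.res_unet = None
        if cfg.variant in ("uur", "concat_unets"):
            self.res_unet = UNetSubnet(
                1, cfg.levels, cfg.res_base_filters, rng,
                cfg.dropout_p, cfg.negative_slope, residual=True,
            )

    def forward(self, x):
        y = self.unet(x)
        if self.res_unet is not None:
            y = self.res_unet(y)
        return y


class PatchDiscriminator(nn.Module):
    def __init__(self, cfg: DiscriminatorConfig, rng):
        super().__init__()
        self.cfg = cfg
        widths = [cfg.base_filters * (1 << i) for i in range(cfg.levels)]
        blocks = []
        c = cfg.in_channels
        for w in widths:
            blocks.append(_ConvBlock(c, w, cfg.filter_size, rng, stride=2, slope=cfg.negative_slope))
            c = w
        self.blocks = blocks
        self.dropout = nn.Dropout(cfg.dropout_p, rng)
        self.head = nn.Conv2d(c, 1, cfg.filter_size, rng, padding="same")
        self.out = nn.Sigmoid()

    def forward(self, x):
        _check_side(x.shape[2], self.cfg.levels)
        _check_side(x.shape[3], self.cfg.levels)
        h = x
        for b in self.blocks:
            h = b(h)
        return self.out(self.head(self.dropout(h)))


def build_generator(cfg: GeneratorConfig | None = None, seed: int = 0) -> NetworkHandle:
    cfg = (cfg or GeneratorConfig()).validate()
    rng = np.random.default_rng(seed)
    return NetworkHandle("generator", cfg, DualUNetGenerator(cfg, rng))


def build_discriminator(cfg: DiscriminatorConfig | None = None, seed: int = 0) -> NetworkHandle:
    cfg = (cfg or DiscriminatorConfig()).validate()
    rng = np.random.default_rng(seed)
    return NetworkHandle("discriminator", cfg, PatchDiscriminator(cfg, rng))


def residual_block(x, block: ResidualBlock):
    """Apply a residual block to a feature map (array or tensor)."""
    return block(x if isinstance(x, nn.Tensor) else nn.Tensor(x))
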