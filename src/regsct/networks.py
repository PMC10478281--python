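"""The three networks of the registration-corrected translation GAN.

* ``Generator`` — ResNet-style image translator: a 7x7 stem, two stride-2
  downsampling convolutions, ``n_residual_blocks`` residual blocks at the
  bottleneck resolution, two stride-2 transposed-convolution upsampling
  blocks, and a 7x7 head with a tanh bounding the output to [-1, 1].
  Reflection padding and instance normalisation throughout.
* ``RegistrationNet`` — a U-Net taking the channel-concatenation of the
  generated image and the (possibly misaligned) reference, emitting a dense
  2-channel displacement field in pixel units.  The final convolution is
  zero-initialised so the network starts from the identity transform.
* ``PatchDiscriminator`` — four 4x4 convolution layers plus a projection,
  mapping an image to an NxN map of real/fake scores, each judging a local
  receptive field.  (Stride 2 for the first three layers, stride 1 after,
  so a 256x256 input yields a 30x30 score map rather than collapsing to a
  single scalar.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, ShapeError
from .layers import Conv2d, ConvTranspose2d, InstanceNorm2d, Module

__all__ = [
    "GeneratorConfig", "RegistrationConfig", "DiscriminatorConfig",
    "Generator", "RegistrationNet", "PatchDiscriminator",
    "build_generator", "build_registration", "build_discriminator",
]


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 1
    base_channels: int = 64
    n_residual_blocks: int = 9
    downsample_stages: int = 2
    upsample_stages: int = 2

    def validate(self) -> None:
        if self.n_residual_blocks < 1:
            raise ConfigurationError("n_residual_blocks must be >= 1")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")
        if self.downsample_stages != 2 or self.upsample_stages != 2:
            raise ConfigurationError("generator uses exactly 2 down/up stages")


@dataclass(frozen=True)
class RegistrationConfig:
    in_channels: int = 2
    encoder_depth: int = 4
    base_channels: int = 16
    out_channels: int = 2

    def validate(self) -> None:
        if self.out_channels != 2:
            raise ConfigurationError("out_channels must equal the spatial dimensionality (2)")
        if self.encoder_depth < 2:
            raise ConfigurationError("encoder_depth must be >= 2")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")


@dataclass(frozen=True)
class DiscriminatorConfig:
    in_channels: int = 1
    n_layers: int = 4
    kernel_size: int = 4
    base_channels: int = 64

    def validate(self) -> None:
        if self.n_layers != 4 or self.kernel_size != 4:
            raise ConfigurationError("discriminator uses 4 layers of 4x4 kernels")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")


class _ResBlock(Module):
    def __init__(self, ch: int, rng: np.random.Generator):
        self.conv1 = Conv2d(ch, ch, 3, rng=rng)
        self.norm1 = InstanceNorm2d(ch)
        self.conv2 = Conv2d(ch, ch, 3, rng=rng)
        self.norm2 = InstanceNorm2d(ch)

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(self.norm1(self.conv1(ad.reflect_pad2d(x, 1))))
        h = self.norm2(self.conv2(ad.reflect_pad2d(h, 1)))
        return ad.add(x, h)


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        b = cfg.base_channels
        self.stem = Conv2d(cfg.in_channels, b, 7, rng=rng)
        self.stem_norm = InstanceNorm2d(b)
        self.down1 = Conv2d(b, 2 * b, 3, stride=2, padding=1, rng=rng)
        self.down1_norm = InstanceNorm2d(2 * b)
        self.down2 = Conv2d(2 * b, 4 * b, 3, stride=2, padding=1, rng=rng)
        self.down2_norm = InstanceNorm2d(4 * b)
        self.blocks = [_ResBlock(4 * b, rng) for _ in range(cfg.n_residual_blocks)]
        self.up1 = ConvTranspose2d(4 * b, 2 * b, 3, rng=rng)
        self.up1_norm = InstanceNorm2d(2 * b)
        self.up2 = ConvTranspose2d(2 * b, b, 3, rng=rng)
        self.up2_norm = InstanceNorm2d(b)
        self.head = Conv2d(b, cfg.in_channels, 7, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ShapeError(f"generator input sides must be divisible by 4, got {x.shape[2:]}")
        h = ad.relu(self.stem_norm(self.stem(ad.reflect_pad2d(x, 3))))
        h = ad.relu(self.down1_norm(self.down1(h)))
        h = ad.relu(self.down2_norm(self.down2(h)))
        for block in self.blocks:
            h = block(h)
        h = ad.relu(self.up1_norm(self.up1(h)))
        h = ad.relu(self.up2_norm(self.up2(h)))
        return ad.tanh(self.head(ad.reflect_pad2d(h, 3)))


class RegistrationNet(Module):
    """U-Net from an image pair to a dense displacement field (pixels)."""

    def __init__(self, cfg: RegistrationConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        b = cfg.base_channels
        chans = [b * (2 ** i) for i in range(cfg.encoder_depth)]
        self.enc = [Conv2d(cfg.in_channels, chans[0], 3, stride=1, padding=1, rng=rng)]
        for i in range(1, cfg.encoder_depth):
            self.enc.append(Conv2d(chans[i - 1], chans[i], 3, stride=2, padding=1, rng=rng))
        self.dec_up = []
        self.dec_conv = []
        for i in range(cfg.encoder_depth - 1, 0, -1):
            self.dec_up.append(ConvTranspose2d(chans[i], chans[i - 1], 3, rng=rng))
            self.dec_conv.append(Conv2d(2 * chans[i - 1], chans[i - 1], 3, padding=1, rng=rng))
        self.head = Conv2d(chans[0], cfg.out_channels, 3, padding=1, rng=rng, zero_init=True)

    def forward(self, a: Tensor, b: Tensor) -> Tensor:
        if a.shape != b.shape:
            raise ShapeError(f"registration inputs differ in shape: {a.shape} vs {b.shape}")
        stride2 = self.cfg.encoder_depth - 1
        if a.shape[2] % (2 ** stride2) or a.shape[3] % (2 ** stride2):
            raise ShapeError(f"input sides must be divisible by {2 ** stride2}")
        h = ad.concat_channels(a, b)
        skips = []
        for conv in self.enc:
            h = ad.leaky_relu(conv(h), 0.2)
            skips.append(h)
        for up, conv, skip in zip(self.dec_up, self.dec_conv, skips[-2::-1]):
            h = ad.leaky_relu(up(h), 0.2)
            h = ad.leaky_relu(conv(ad.concat_channels(h, skip)), 0.2)
        return self.head(h)


class PatchDiscriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        b = cfg.base_channels
        k = cfg.kernel_size
        self.conv1 = Conv2d(cfg.in_channels, b, k, stride=2, padding=1, rng=rng)
        self.conv2 = Conv2d(b, 2 * b, k, stride=2, padding=1, rng=rng)
        self.norm2 = InstanceNorm2d(2 * b)
        self.conv3 = Conv2d(2 * b, 4 * b, k, stride=2, padding=1, rng=rng)
        self.norm3 = InstanceNorm2d(4 * b)
        self.conv4 = Conv2d(4 * b, 8 * b, k, stride=1, padding=1, rng=rng)
        self.norm4 = InstanceNorm2d(8 * b)
        self.proj = Conv2d(8 * b, 1, k, stride=1, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = ad.leaky_relu(self.conv1(x), 0.2)
        h = ad.leaky_relu(self.norm2(self.conv2(h)), 0.2)
        h = ad.leaky_relu(self.norm3(self.conv3(h)), 0.2)
        h = ad.leaky_relu(self.norm4(self.conv4(h)), 0.2)
        return self.proj(h)


def build_generator(cfg: GeneratorConfig | None = None, seed: int = 0) -> Generator:
    return Generator(cfg or GeneratorConfig(), np.random.default_rng(seed))


def build_registration(cfg: RegistrationConfig | None = None, seed: int = 0) -> RegistrationNet:
    return RegistrationNet(cfg or RegistrationConfig(), np.random.default_rng(seed))


def build_discriminator(cfg: DiscriminatorConfig | None = None, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(cfg or DiscriminatorConfig(), np.random.default_rng(seed))
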