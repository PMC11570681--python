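"""Dual-input residual U-net generator and LSGAN patch discriminator.

Architecture
------------
The generator takes the real/imaginary channels of a zero-filled
undersampled FLAIR image and, in dual-input mode, the real/imaginary
channels of a fully sampled T2WI reference of the same slice.  Each
branch passes a 32-channel residual stem; the stem features are
concatenated and fed to a U-net body: four downsampling stages (2x2 max
pooling) of residual blocks starting at 128 channels and doubling per
stage, a bottleneck, and a mirrored upsampling path of transposed
convolutions and residual blocks halving the channel count, with
encoder-to-decoder skip concatenations.  A long skip connection adds the
undersampled input to the body's output, so the network learns the
residual between undersampled and fully sampled images — zeroing the
final convolution makes the generator an exact identity.

Each residual block is two (3x3 convolution, batch norm, ReLU) units
with an identity shortcut (1x1 projection when the channel count
changes).  The discriminator is a patch-level stack of stride-2
convolutions with no terminal squashing; its raw scores feed the
least-squares adversarial objectives.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, asdict, field

import numpy as np

from .errors import ConfigurationError, DimensionError
from .kspace import ifft2c, rss_combine
from .nnet import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    LeakyReLU,
    MaxPool2d,
    Param,
    ReLU,
)

__all__ = [
    "ReconNetConfig",
    "DiscriminatorConfig",
    "ResidualBlock",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "normalization_scale",
    "reconstruct_case",
]


@dataclass(frozen=True)
class ReconNetConfig:
    """Declarative description of the generator.

    Defaults mirror the full-scale architecture (32-channel stems, U-net
    encoder starting at 128 channels over four scales).  Desk-scale
    experiments shrink ``stem_channels`` / ``encoder_base_channels`` /
    ``n_scales`` without changing the wiring.
    """

    stem_channels: int = 32
    encoder_base_channels: int = 128
    n_scales: int = 4
    use_reference_branch: bool = True
    in_channels_per_branch: int = 2
    out_channels: int = 2
    long_skip: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReconNetConfig":
        return cls(**d)


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Patch discriminator: ``n_layers`` stride-2 stages from ``base_channels``."""

    n_layers: int = 4
    base_channels: int = 64
    in_channels: int = 2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminatorConfig":
        return cls(**d)


class ResidualBlock(Layer):
    """Two (conv3x3, BN, ReLU) units with an identity/projection shortcut."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_channels, out_channels, 3, 1, 1, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, 1, 1, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.relu_out = ReLU()
        if in_channels != out_channels:
            self.shortcut: Conv2d | None = Conv2d(
                in_channels, out_channels, 1, 1, 0, rng=rng
            )
        else:
            self.shortcut = None
        self._children: list[Layer] = [
            l
            for l in (self.conv1, self.bn1, self.conv2, self.bn2, self.shortcut)
            if l is not None
        ]

    def parameters(self) -> list[Param]:
        return [p for l in self._children for p in l.parameters()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        for i, l in enumerate(self._children):
            for k, v in l.state_arrays().items():
                d[f"c{i}.{k}"] = v
        return d

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, train), train), train
        )
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu_out.forward(h + s, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = self.relu_out.backward(dy)
        dh = self.bn2.backward(dz)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.shortcut is None:
            dx = dx + dz
        else:
            dx = dx + self.shortcut.backward(dz)
        return dx


class Generator(Layer):
    """Callable reconstruction network built from a :class:`ReconNetConfig`."""

    def __init__(self, config: ReconNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cin = config.in_channels_per_branch
        stem = config.stem_channels
        base = config.encoder_base_channels
        ns = config.n_scales

        self.stem_under = ResidualBlock(cin, stem, rng)
        self.stem_ref = ResidualBlock(cin, stem, rng) if config.use_reference_branch else None
        branches = 2 if config.use_reference_branch else 1

        self.enc_blocks: list[ResidualBlock] = []
        for s in range(ns):
            in_ch = stem * branches if s == 0 else base * 2 ** (s - 1)
            self.enc_blocks.append(ResidualBlock(in_ch, base * 2**s, rng))
        self.pools = [MaxPool2d() for _ in range(ns)]
        self.bottleneck = ResidualBlock(base * 2 ** (ns - 1), base * 2**ns, rng)

        self.upconvs: list[ConvTranspose2d] = []
        self.dec_blocks: list[ResidualBlock] = []
        for s in range(ns - 1, -1, -1):
            ch = base * 2**s
            self.upconvs.append(ConvTranspose2d(ch * 2, ch, rng))
            self.dec_blocks.append(ResidualBlock(ch * 2, ch, rng))

        self.final_conv = Conv2d(base, config.out_channels, 3, 1, 1, rng=rng)
        self._children: list[Layer] = [self.stem_under]
        if self.stem_ref is not None:
            self._children.append(self.stem_ref)
        self._children += self.enc_blocks + [self.bottleneck]
        self._children += self.upconvs + self.dec_blocks + [self.final_conv]
        self._cache: dict | None = None

    # -- structure ---------------------------------------------------------
    def parameters(self) -> list[Param]:
        return [p for l in self._children for p in l.parameters()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        for i, l in enumerate(self._children):
            for k, v in l.state_arrays().items():
                d[f"m{i}.{k}"] = v
        return d

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(state):
            raise ConfigurationError("checkpoint does not match this architecture")
        for k, dst in own.items():
            dst[...] = state[k]

    def zero_residual_branch(self) -> None:
        """Zero the output convolution: the long skip then makes an identity."""
        self.final_conv.weight.data[...] = 0.0
        self.final_conv.bias.data[...] = 0.0

    # -- compute -----------------------------------------------------------
    def _check_inputs(self, x: np.ndarray, ref: np.ndarray | None) -> None:
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != cfg.in_channels_per_branch:
            raise DimensionError(
                f"expected N x {cfg.in_channels_per_branch} x H x W input, got {x.shape}"
            )
        h, w = x.shape[2], x.shape[3]
        div = 2**cfg.n_scales
        if h % div or w % div:
            raise DimensionError(
                f"spatial size {h}x{w} must be divisible by 2^{cfg.n_scales}"
            )
        if cfg.use_reference_branch and ref is None:
            raise ConfigurationError("dual-input model requires a reference image")
        if not cfg.use_reference_branch and ref is not None:
            raise ConfigurationError("single-input model accepts no reference image")
        if ref is not None and ref.shape != x.shape:
            raise DimensionError("reference shape must match the undersampled input")

    def forward(
        self, x: np.ndarray, ref: np.ndarray | None = None, train: bool = False
    ) -> np.ndarray:
        self._check_inputs(x, ref)
        su = self.stem_under.forward(x, train)
        if self.stem_ref is not None:
            sr = self.stem_ref.forward(ref, train)
            f = np.concatenate([su, sr], axis=1)
        else:
            f = su
        skips: list[np.ndarray] = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            f = blk.forward(f, train)
            skips.append(f)
            f = pool.forward(f, train)
        f = self.bottleneck.forward(f, train)
        for up, dec, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            f = up.forward(f, train)
            f = dec.forward(np.concatenate([f, skip], axis=1), train)
        y = self.final_conv.forward(f, train)
        if self.config.long_skip:
            y = y + x
        if train:
            self._cache = {"stem_ch": su.shape[1]}
        return y

    def __call__(self, x: np.ndarray, ref: np.ndarray | None = None) -> np.ndarray:
        return self.forward(x, ref, train=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Propagate; returns gradient w.r.t. the undersampled input."""
        assert self._cache is not None
        df = self.final_conv.backward(dy)
        for up, dec in zip(reversed(self.upconvs), reversed(self.dec_blocks)):
            dcat = dec.backward(df)
            ch = dcat.shape[1] // 2
            dup, dskip = dcat[:, :ch], dcat[:, ch:]
            df = up.backward(dup)
            # stash skip gradients to add on the way back through the encoder
            up._dskip = dskip  # type: ignore[attr-defined]
        df = self.bottleneck.backward(df)
        for blk, pool, up in zip(
            reversed(self.enc_blocks), reversed(self.pools), self.upconvs
        ):
            df = pool.backward(df)
            df = df + up._dskip  # type: ignore[attr-defined]
            up._dskip = None  # type: ignore[attr-defined]
            df = blk.backward(df)
        stem_ch = self._cache["stem_ch"]
        self._cache = None
        if self.stem_ref is not None:
            du, dr = df[:, :stem_ch], df[:, stem_ch:]
            self.stem_ref.backward(dr)
            dx = self.stem_under.backward(du)
        else:
            dx = self.stem_under.backward(df)
        if self.config.long_skip:
            dx = dx + dy
        return dx


class Discriminator(Layer):
    """Stride-2 patch critic emitting an unbounded real score map."""

    def __init__(self, config: DiscriminatorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list[Layer] = [
            Conv2d(config.in_channels, config.base_channels, 4, 2, 1, rng=rng),
            LeakyReLU(0.2),
        ]
        ch = config.base_channels
        for _ in range(config.n_layers - 1):
            layers += [Conv2d(ch, ch * 2, 4, 2, 1, rng=rng), BatchNorm2d(ch * 2), LeakyReLU(0.2)]
            ch *= 2
        layers.append(Conv2d(ch, 1, 3, 1, 1, rng=rng))
        self.layers = layers

    def parameters(self) -> list[Param]:
        return [p for l in self.layers for p in l.parameters()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        for i, l in enumerate(self.layers):
            for k, v in l.state_arrays().items():
                d[f"d{i}.{k}"] = v
        return d

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4:
            raise DimensionError("discriminator expects N x C x H x W input")
        min_size = 2**self.config.n_layers
        if x.shape[2] < min_size or x.shape[3] < min_size:
            raise DimensionError(
                f"input {x.shape[2]}x{x.shape[3]} smaller than the receptive "
                f"field ({min_size}x{min_size})"
            )
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def build_generator(config: ReconNetConfig, seed: int = 0) -> Generator:
    """Instantiate a generator with seeded He-initialized weights."""
    return Generator(config, seed=seed)


def build_discriminator(config: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    return Discriminator(config, seed=seed)


def normalization_scale(images: np.ndarray, percentile: float = 99.0) -> float:
    """Per-case intensity scale: the 99th percentile of the magnitude.

    Keeps network inputs and LSGAN targets in a fixed numeric range; the
    scale is inverted on the network output so reconstructions return to
    physical units.
    """
    mags = np.abs(np.asarray(images))
    scale = float(np.percentile(mags, percentile))
    return scale if scale > 0 else 1.0


def _to_channels(img: np.ndarray) -> np.ndarray:
    return np.stack([img.real, img.imag], axis=0)


def reconstruct_case(
    generator: Generator,
    k_masked: np.ndarray,
    reference_images: np.ndarray | None = None,
    combine: bool = True,
) -> np.ndarray:
    """Reconstruct one slice from masked multi-coil k-space.

    Every coil is processed sequentially: the zero-filled coil image (and
    the matching reference coil image, for dual-input models) is split
    into real/imaginary channels, normalized by the per-case scale, run
    through the generator, and reassembled into a complex image.  With
    ``combine=True`` the coil images are merged by root-sum-of-squares
    into a magnitude image; otherwise the complex coil stack is returned.
    """
    k_masked = np.asarray(k_masked)
    if k_masked.ndim == 2:
        k_masked = k_masked[None]
    zf = ifft2c(k_masked)
    dual = generator.config.use_reference_branch
    if dual:
        if reference_images is None:
            raise ConfigurationError("dual-input generator requires reference images")
        reference_images = np.asarray(reference_images)
        if reference_images.ndim == 2:
            reference_images = reference_images[None]
        if reference_images.shape[0] != zf.shape[0]:
            raise DimensionError(
                f"reference has {reference_images.shape[0]} coils, "
                f"k-space has {zf.shape[0]}"
            )
    elif reference_images is not None:
        raise ConfigurationError("single-input generator accepts no reference images")

    scale_u = normalization_scale(zf)
    scale_r = normalization_scale(reference_images) if dual else 1.0
    out = np.empty_like(zf)
    for c in range(zf.shape[0]):
        x = _to_channels(zf[c] / scale_u)[None]
        ref = _to_channels(reference_images[c] / scale_r)[None] if dual else None
        y = generator(x, ref)[0]
        out[c] = (y[0] + 1j * y[1]) * scale_u
    return rss_combine(out) if combine else out


def clone_generator(generator: Generator) -> Generator:
    """Deep copy (weights, running stats, config) — used for checkpointing."""
    return copy.deepcopy(generator)
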