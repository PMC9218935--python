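"""Reusable layer specifications and their forward semantics.

These are the building blocks every architecture in this package is
assembled from: plain convolution blocks, Ghost modules, pooling,
bilinear upsampling, transposed convolution, and the additive
full-scale fusion node. Each block has a declarative spec (used by the
analytic complexity engine) and a numpy forward implementation (used by
the runtime).

Feature maps are (batch, channels, height, width) float32 arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    ConvLayer,
    DeconvLayer,
    GhostLayer,
    MaxPoolLayer,
    ShapeError,
    UnsupportedConfigError,
    bilinear_fwd,
)

__all__ = [
    "ConvSpec",
    "GhostSpec",
    "DeconvSpec",
    "FusionSpec",
    "ShapeError",
    "UnsupportedConfigError",
    "conv_forward",
    "ghost_forward",
    "deconv_forward",
    "maxpool2",
    "bilinear_up",
    "full_scale_fusion",
    "init_layer",
]


@dataclass(frozen=True)
class ConvSpec:
    """A stride-1, "same"-padded K x K convolution.

    ``has_bias`` adds one bias per output channel; ``with_batchnorm`` adds a
    learned per-channel scale and shift after the convolution.
    """

    kernel_size: int
    in_channels: int
    out_channels: int
    has_bias: bool = True
    with_batchnorm: bool = False
    with_relu: bool = False

    def __post_init__(self):
        if self.kernel_size < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise UnsupportedConfigError(f"invalid conv spec {self}")


@dataclass(frozen=True)
class GhostSpec:
    """A Ghost module with ratio s (reciprocal of the intrinsic-map
    proportion). Only s=2 is supported: half of the output channels come
    from a primary K x K convolution ("intrinsic" maps), the other half
    from a cheap d x d depthwise convolution of the intrinsic maps.
    """

    kernel_size: int
    in_channels: int
    out_channels: int
    ratio: int = 2
    cheap_kernel: int = 3
    with_batchnorm: bool = True
    with_relu: bool = True

    def __post_init__(self):
        if self.ratio != 2:
            raise UnsupportedConfigError(
                f"Ghost ratio s={self.ratio} unsupported; only s=2 is calibrated"
            )
        if self.out_channels % self.ratio:
            raise UnsupportedConfigError(
                f"Ghost out_channels={self.out_channels} not divisible by s={self.ratio}"
            )


@dataclass(frozen=True)
class DeconvSpec:
    """Transposed convolution with stride equal to its kernel size, so the
    output is exactly ``kernel_size`` times larger in each spatial dim."""

    kernel_size: int
    in_channels: int
    out_channels: int
    input_height: int | None = None
    input_width: int | None = None

    @property
    def stride(self) -> int:
        return self.kernel_size


@dataclass(frozen=True)
class FusionSpec:
    """A feature-fusion node. ``add`` requires equal channel counts and
    (after upsampling) equal spatial sizes; ``concat`` stacks channels."""

    mode: str  # "add" | "concat"
    input_count: int
    input_scales: tuple = ()

    def __post_init__(self):
        if self.mode not in ("add", "concat"):
            raise UnsupportedConfigError(f"unknown fusion mode {self.mode!r}")


# ---------------------------------------------------------------------------
# functional forwards (thin wrappers over engine layers)


def init_layer(spec, seed=0):
    """Instantiate an engine layer (with Kaiming-initialized weights) for a
    block spec. Useful for exercising a single block outside a network."""
    rng = np.random.default_rng(seed)
    if isinstance(spec, ConvSpec):
        return ConvLayer(
            spec.kernel_size,
            spec.in_channels,
            spec.out_channels,
            rng,
            bias=spec.has_bias,
            batchnorm=spec.with_batchnorm,
            relu=spec.with_relu,
        )
    if isinstance(spec, GhostSpec):
        return GhostLayer(
            spec.kernel_size,
            spec.in_channels,
            spec.out_channels,
            rng,
            s=spec.ratio,
            d=spec.cheap_kernel,
            batchnorm=spec.with_batchnorm,
            relu=spec.with_relu,
        )
    if isinstance(spec, DeconvSpec):
        return DeconvLayer(spec.kernel_size, spec.in_channels, spec.out_channels, rng)
    raise UnsupportedConfigError(f"cannot instantiate {spec!r}")


def conv_forward(x, spec: ConvSpec, layer: ConvLayer | None = None, seed=0):
    layer = layer or init_layer(spec, seed)
    return layer.forward([np.asarray(x, dtype=np.float32)], training=False)


def ghost_forward(x, spec: GhostSpec, layer: GhostLayer | None = None, seed=0):
    """Run a Ghost module forward: output channels are the concatenation of
    Cout/2 intrinsic maps and Cout/2 cheap depthwise maps; spatial size is
    preserved."""
    x = np.asarray(x, dtype=np.float32)
    if x.shape[1] != spec.in_channels:
        raise ShapeError(
            f"ghost expects {spec.in_channels} input channels, got {x.shape[1]}"
        )
    layer = layer or init_layer(spec, seed)
    return layer.forward([x], training=False)


def deconv_forward(x, spec: DeconvSpec, layer: DeconvLayer | None = None, seed=0):
    layer = layer or init_layer(spec, seed)
    return layer.forward([np.asarray(x, dtype=np.float32)], training=False)


def maxpool2(x):
    """2x2 stride-2 max pooling; input spatial dims must be even."""
    return MaxPoolLayer().forward([np.asarray(x, dtype=np.float32)], training=False)


def bilinear_up(x, factor: int):
    """Bilinear upsampling by an integer factor (half-pixel centers,
    edge-clamped); a constant map stays constant."""
    return bilinear_fwd(np.asarray(x, dtype=np.float32), int(factor))


def full_scale_fusion(features):
    """Additive full-scale feature fusion.

    Each input map (at a power-of-two fraction of the full size) is
    bilinearly upsampled to the size of the largest map, then all maps are
    summed elementwise. All inputs must share the channel count — addition,
    unlike concatenation, cannot absorb a mismatch — and the node introduces
    no learnable parameters.
    """
    features = [np.asarray(f, dtype=np.float32) for f in features]
    channels = {f.shape[1] for f in features}
    if len(channels) != 1:
        raise ShapeError(f"additive fusion requires one channel count, got {channels}")
    full = max(f.shape[2] for f in features)
    out = None
    for f in features:
        if full % f.shape[2] or full % f.shape[3]:
            raise ShapeError(
                f"map size {f.shape[2:]} is not an integer fraction of {full}"
            )
        up = bilinear_fwd(f, full // f.shape[2])
        out = up.copy() if out is None else out + up
    return out
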