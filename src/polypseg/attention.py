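"""The three attention/fusion blocks of the architecture.

SSIA (semantic and spatial information aggregation) fuses the stem features
(rich in spatial detail) with the deepest encoder features (rich in
semantics) into a single-channel coarse mask that both receives the local
deep-supervision loss and gates the skip connections.

DSFF (deep-supervision feature fusion) multiplies each encoder tap by the
SSIA mask probability (bilinearly resized), adds the mask back as a residual,
refines with a 3×3 convolution, and rescales channels by a squeeze-style
sigmoid of the global average pool.

EFE (efficient feature extraction) is the decoder block: four parallel
convolutions with kernels 3/5/7/9 split the output width, a per-branch
channel-attention bottleneck produces channel weights, a 7×7 spatial
submodule on the block input produces one spatial plane, and the trunk is
modulated by (channel weights + spatial plane).

All resampling uses one bilinear half-pixel convention so the mask and the
gates sample identically.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import ConfigError
from .grad import engine
from .grad.layers import BatchNorm2d, Conv2d, Module, conv_bn_relu


@dataclasses.dataclass
class SSIAMask:
    """Coarse mask at stem resolution: raw logits and their sigmoid."""

    logits: engine.Tensor
    probability: engine.Tensor


class SSIA(Module):
    """Aggregate stem and deepest-encoder features into a 1-channel mask.

    Both inputs are projected to a common width by 1×1 convolutions, the
    deep branch is bilinearly interpolated to stem resolution, the branches
    are channel-concatenated, refined by two 3×3 conv+norm+ReLU stages, and
    reduced to one channel of logits.
    """

    def __init__(self, low_channels, high_channels, mid_channels=64, rng=None):
        super().__init__()
        self.low_proj = Conv2d(low_channels, mid_channels, 1, rng=rng)
        self.high_proj = Conv2d(high_channels, mid_channels, 1, rng=rng)
        self.refine1 = conv_bn_relu(2 * mid_channels, mid_channels, 3, padding=1, rng=rng)
        self.refine2 = conv_bn_relu(mid_channels, mid_channels, 3, padding=1, rng=rng)
        self.head = Conv2d(mid_channels, 1, 1, rng=rng)

    def forward(self, low, high) -> SSIAMask:
        low, high = engine.as_tensor(low), engine.as_tensor(high)
        if low.shape[0] != high.shape[0]:
            raise ConfigError(
                f"batch mismatch between SSIA inputs: {low.shape[0]} vs {high.shape[0]}")
        b1 = self.low_proj(low)
        b2 = engine.interpolate_bilinear(self.high_proj(high), low.shape[2:])
        fused = engine.concat([b1, b2], axis=1)
        logits = self.head(self.refine2(self.refine1(fused)))
        return SSIAMask(logits=logits, probability=engine.sigmoid(logits))


def channel_attention(x):
    """Squeeze-style channel rescaling: x ⊙ σ(global average pool per channel)."""
    return engine.mul(engine.sigmoid(engine.global_avg_pool(x)), x)


class DSFF(Module):
    """Mask-guided fusion of one encoder tap.

    With a mask: ``X' = Conv3×3(E ⊙ τ(m) + τ(m))`` where τ is bilinear
    resizing of the 1-channel mask probability to the tap's resolution
    (broadcast over channels), followed by channel attention
    ``σ(avgpool(X')) ⊙ X'``.  Without a mask (deep-supervision ablation) the
    block degenerates to channel attention on ``Conv3×3(E)``.

    ``residual='mask'`` adds the resized mask as the residual term (default);
    ``residual='feature'`` adds the gated tap's source feature instead.
    """

    def __init__(self, channels, rng=None, residual="mask"):
        super().__init__()
        if residual not in ("mask", "feature"):
            raise ConfigError(f"unknown DSFF residual mode {residual!r}")
        self.residual = residual
        self.refine = Conv2d(channels, channels, 3, padding=1, bias=True, rng=rng)

    def forward(self, e, mask: SSIAMask | None = None):
        e = engine.as_tensor(e)
        if mask is None:
            refined = self.refine(e)
        else:
            prob = mask.probability
            if prob.shape[1] != 1:
                raise ConfigError(
                    f"DSFF expects a 1-channel mask, got {prob.shape[1]} channels")
            m = engine.interpolate_bilinear(prob, e.shape[2:])
            residual = m if self.residual == "mask" else e
            refined = self.refine(engine.mul(e, m) + residual)
        return channel_attention(refined)


class EFE(Module):
    """Multi-kernel decoder block with channel and spatial attention."""

    def __init__(self, in_channels, out_channels, kernels=(3, 5, 7, 9),
                 reduction=4, rng=None):
        super().__init__()
        kernels = tuple(kernels)
        if out_channels % len(kernels) != 0:
            raise ConfigError(
                f"out_channels {out_channels} not divisible by the "
                f"{len(kernels)} parallel kernels")
        branch_ch = out_channels // len(kernels)
        if branch_ch // reduction < 1:
            raise ConfigError(
                f"branch width {branch_ch} too small for reduction ratio {reduction}")
        self.kernels = kernels
        self.branches = [
            conv_bn_relu(in_channels, branch_ch, k, padding=k // 2, rng=rng)
            for k in kernels
        ]
        hidden = branch_ch // reduction
        self.channel_fcs = [
            # bottleneck on the pooled (B, C, 1, 1) descriptor
            _ChannelGate(branch_ch, hidden, rng=rng)
            for _ in kernels
        ]
        self.spatial_conv = Conv2d(2, 1, 7, padding=3, rng=rng)

    def spatial_attention(self, x):
        """One sigmoid plane from channelwise mean- and max-pooled input."""
        x = engine.as_tensor(x)
        mean_plane = engine.tmean(x, axis=1, keepdims=True)
        max_plane = engine.tmax(x, axis=1, keepdims=True)
        stacked = engine.concat([mean_plane, max_plane], axis=1)
        return engine.sigmoid(self.spatial_conv(stacked))

    def forward(self, x):
        x = engine.as_tensor(x)
        trunk_parts = [branch(x) for branch in self.branches]
        channel_parts = [gate(part) for gate, part in
                         zip(self.channel_fcs, trunk_parts)]
        trunk = engine.concat(trunk_parts, axis=1)
        channel_w = engine.concat(channel_parts, axis=1)  # (B, C, 1, 1)
        spatial_w = self.spatial_attention(x)             # (B, 1, H, W)
        return engine.mul(trunk, channel_w + spatial_w)


class _ChannelGate(Module):
    """Global average pool → bottleneck → sigmoid per-channel weights.

    The bottleneck uses a leaky rectifier: the pooled descriptor is a single
    value per channel, so with a hard rectifier a narrow bottleneck can start
    with every hidden unit inactive across a whole batch and never receive
    gradient.  A 0.01 slope keeps every gate trainable at any width.
    """

    def __init__(self, channels, hidden, rng=None):
        super().__init__()
        self.fc1 = Conv2d(channels, hidden, 1, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng=rng)

    def forward(self, x):
        pooled = engine.global_avg_pool(x)
        return engine.sigmoid(self.fc2(engine.leaky_relu(self.fc1(pooled))))
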