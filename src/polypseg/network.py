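"""Full network assembly: encoder → SSIA → DSFF skips → EFE decoder → head.

The decoder starts from the gated deepest tap, then at each level upsamples
×2, concatenates the gated skip at that scale, and applies a decoder block
(EFE by default).  The head carries the stride-4 decoder output back to full
resolution with two upsample + 3×3 refinement steps and a 1×1 sigmoid
projection, avoiding a single ×4 jump.

Ablation switches reproduce the component-removal variants:

``use_efe=False``
    each EFE is replaced by two 3×3 conv+norm+ReLU stages (the plain
    residual-encoder U-Net-style baseline decoder);
``use_ssia=False``
    no auxiliary mask is produced and DSFF degenerates to channel attention
    on a 3×3 refinement of the tap;
``use_dsff=False``
    raw encoder taps are used as skips (the SSIA mask, if enabled, still
    feeds the local loss);
``use_local_loss=False``
    handled by the loss/trainer: the auxiliary term is dropped from the
    objective while the mask still gates the skips.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import yaml

from .attention import DSFF, EFE, SSIA, SSIAMask
from .encoder import ResNetEncoder
from .exceptions import ConfigError
from .grad import engine
from .grad.layers import Conv2d, Module, Sequential, conv_bn_relu


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters and ablation switches."""

    filters: tuple = (32, 64, 128, 256, 512)
    input_size: int = 256
    efe_kernels: tuple = (3, 5, 7, 9)
    efe_reduction: int = 4
    decoder_widths: tuple = (256, 128, 64, 32)
    ssia_mid_channels: int = 64
    head_width: int = 16
    use_efe: bool = True
    use_ssia: bool = True
    use_local_loss: bool = True
    use_dsff: bool = True

    def __post_init__(self):
        object.__setattr__(self, "filters", tuple(int(f) for f in self.filters))
        object.__setattr__(self, "efe_kernels", tuple(int(k) for k in self.efe_kernels))
        object.__setattr__(self, "decoder_widths", tuple(int(w) for w in self.decoder_widths))
        if self.input_size % 32 != 0:
            raise ConfigError(f"input_size must be divisible by 32, got {self.input_size}")
        if len(self.filters) != 5:
            raise ConfigError(f"filters needs exactly 5 entries, got {self.filters}")
        if len(self.decoder_widths) != 4:
            raise ConfigError(f"decoder_widths needs 4 entries, got {self.decoder_widths}")
        if self.use_efe:
            n = len(self.efe_kernels)
            for w in self.decoder_widths:
                if w % n != 0 or w % 4 != 0:
                    raise ConfigError(
                        f"decoder width {w} must be divisible by 4 (kernel branches)")

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["filters"] = list(self.filters)
        d["efe_kernels"] = list(self.efe_kernels)
        d["decoder_widths"] = list(self.decoder_widths)
        return d

    @classmethod
    def from_dict(cls, d):
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclasses.dataclass
class NetworkOutput:
    """Full-resolution probability map plus the auxiliary SSIA mask (if any)."""

    prediction: engine.Tensor
    aux_mask: SSIAMask | None = None


def _double_conv(in_ch, out_ch, rng):
    """Two 3×3 conv+norm+ReLU stages (EFE ablation / baseline decoder block)."""
    return Sequential(
        conv_bn_relu(in_ch, out_ch, 3, padding=1, rng=rng),
        conv_bn_relu(out_ch, out_ch, 3, padding=1, rng=rng),
    )


class DLGRAFENet(Module):
    """Double-loss guided residual attention and feature enhancement network."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = config or NetworkConfig()
        self.config = cfg
        rng = np.random.default_rng(seed)
        f = cfg.filters
        dw = cfg.decoder_widths

        self.encoder = ResNetEncoder(filters=f, rng=rng)
        if cfg.use_ssia:
            self.ssia = SSIA(low_channels=f[0], high_channels=f[4],
                             mid_channels=cfg.ssia_mid_channels, rng=rng)
        else:
            self.ssia = None
        if cfg.use_dsff:
            # one fusion block per tap, deepest first (e16, e13, e7, e3)
            self.dsff = [DSFF(ch, rng=rng) for ch in (f[4], f[3], f[2], f[1])]
        else:
            self.dsff = None

        skip_ch = (f[4], f[3], f[2], f[1])

        def block(in_ch, out_ch):
            if cfg.use_efe:
                return EFE(in_ch, out_ch, kernels=cfg.efe_kernels,
                           reduction=cfg.efe_reduction, rng=rng)
            return _double_conv(in_ch, out_ch, rng)

        self.decoder = [
            block(skip_ch[0], dw[0]),
            block(dw[0] + skip_ch[1], dw[1]),
            block(dw[1] + skip_ch[2], dw[2]),
            block(dw[2] + skip_ch[3], dw[3]),
        ]
        hw = cfg.head_width
        self.head_refine1 = conv_bn_relu(dw[3], hw, 3, padding=1, rng=rng)
        self.head_refine2 = conv_bn_relu(hw, hw, 3, padding=1, rng=rng)
        self.head_proj = Conv2d(hw, 1, 1, rng=rng)

    # -- forward --------------------------------------------------------------

    def forward(self, image) -> NetworkOutput:
        image = engine.as_tensor(image)
        taps = self.encoder(image)
        aux = self.ssia(taps.stem, taps.e16) if self.ssia is not None else None

        skips = taps.skip_list()  # deepest first
        if self.dsff is not None:
            gate = aux if self.config.use_ssia else None
            skips = [blk(s, gate) for blk, s in zip(self.dsff, skips)]

        d = self.decoder[0](skips[0])
        for level in (1, 2, 3):
            up = engine.interpolate_bilinear(
                d, (d.shape[2] * 2, d.shape[3] * 2))
            d = self.decoder[level](engine.concat([up, skips[level]], axis=1))

        h = engine.interpolate_bilinear(d, (d.shape[2] * 2, d.shape[3] * 2))
        h = self.head_refine1(h)
        h = engine.interpolate_bilinear(h, (h.shape[2] * 2, h.shape[3] * 2))
        h = self.head_refine2(h)
        prediction = engine.sigmoid(self.head_proj(h))
        return NetworkOutput(prediction=prediction, aux_mask=aux)

    # -- introspection ---------------------------------------------------------

    def parameter_census(self) -> dict:
        """Trainable-parameter counts per top-level component, plus the total."""
        groups = {"encoder": self.encoder}
        if self.ssia is not None:
            groups["ssia"] = self.ssia
        if self.dsff is not None:
            for i, name in enumerate(("dsff16", "dsff13", "dsff7", "dsff3")):
                groups[name] = self.dsff[i]
        for i, name in enumerate(("decoder4", "decoder3", "decoder2", "decoder1")):
            groups[name] = self.decoder[i]
        groups["head"] = Sequential(self.head_refine1, self.head_refine2, self.head_proj)
        census = {name: mod.num_parameters() for name, mod in groups.items()}
        census["total"] = sum(census.values())
        return census
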