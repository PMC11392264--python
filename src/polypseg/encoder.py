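"""Residual encoder: 7×7 stem plus a ResNet34-style four-stage body.

The encoder exposes taps after residual blocks 3, 7, 13 and 16 — the stage
boundaries of the 3/4/6/3 block layout — at strides 4, 8, 16 and 32, plus the
stem activation at stride 2.  Channel widths are configurable; the default
follows the compact [32, 64, 128, 256, 512] filter set, while the pretrained
import path requires the standard ResNet34 widths [64, 64, 128, 256, 512].
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np

from .exceptions import ConfigError, IncompatibleWeightsError
from .grad import engine
from .grad.layers import BatchNorm2d, Conv2d, Module, ReLU, Sequential

RESNET34_BLOCKS = (3, 4, 6, 3)
RESNET34_FILTERS = (64, 64, 128, 256, 512)


@dataclasses.dataclass
class EncoderTaps:
    """Encoder activations: stem at stride 2; e3/e7/e13/e16 at strides 4..32."""

    stem: engine.Tensor
    e3: engine.Tensor
    e7: engine.Tensor
    e13: engine.Tensor
    e16: engine.Tensor

    def skip_list(self):
        """Taps in decoder order: deepest first."""
        return [self.e16, self.e13, self.e7, self.e3]


class BasicBlock(Module):
    """Two 3×3 conv+norm stages with a residual shortcut.

    The shortcut is the identity when shape is preserved and a strided 1×1
    projection (with normalization) otherwise; rectification follows the sum.
    """

    def __init__(self, in_channels, out_channels, stride=1, rng=None):
        super().__init__()
        if stride not in (1, 2):
            raise ConfigError(f"residual block stride must be 1 or 2, got {stride}")
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride,
                            padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, stride=1,
                            padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        if stride != 1 or in_channels != out_channels:
            self.downsample = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride,
                       bias=False, rng=rng),
                BatchNorm2d(out_channels),
            )
        else:
            self.downsample = None

    def forward(self, x):
        out = engine.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        shortcut = self.downsample(x) if self.downsample is not None else x
        return engine.relu(out + shortcut)


def residual_block(x, block: BasicBlock):
    """Functional form of one residual block (used by oracle tests)."""
    return block(x)


class ResNetEncoder(Module):
    """7×7 stride-2 stem, stride-2 max-pool, then four residual stages."""

    def __init__(self, filters=(32, 64, 128, 256, 512), rng=None):
        super().__init__()
        if len(filters) != 5:
            raise ConfigError(f"filters must have 5 entries, got {filters}")
        self.filters = tuple(int(f) for f in filters)
        f0, f1, f2, f3, f4 = self.filters
        self.conv1 = Conv2d(3, f0, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(f0)
        self.relu = ReLU()
        self.layer1 = self._make_stage(f0, f1, RESNET34_BLOCKS[0], stride=1, rng=rng)
        self.layer2 = self._make_stage(f1, f2, RESNET34_BLOCKS[1], stride=2, rng=rng)
        self.layer3 = self._make_stage(f2, f3, RESNET34_BLOCKS[2], stride=2, rng=rng)
        self.layer4 = self._make_stage(f3, f4, RESNET34_BLOCKS[3], stride=2, rng=rng)

    @staticmethod
    def _make_stage(in_ch, out_ch, n_blocks, stride, rng):
        blocks = [BasicBlock(in_ch, out_ch, stride=stride, rng=rng)]
        blocks.extend(BasicBlock(out_ch, out_ch, stride=1, rng=rng)
                      for _ in range(n_blocks - 1))
        return Sequential(*blocks)

    def num_blocks(self) -> int:
        return sum(len(stage.mods) for stage in
                   (self.layer1, self.layer2, self.layer3, self.layer4))

    def forward(self, x) -> EncoderTaps:
        x = engine.as_tensor(x)
        h, w = x.shape[2], x.shape[3]
        if h % 32 != 0 or w % 32 != 0:
            raise ConfigError(f"input spatial size must be divisible by 32, got {h}x{w}")
        stem = self.relu(self.bn1(self.conv1(x)))
        pooled = engine.maxpool2d(stem, kernel=3, stride=2, padding=1)
        e3 = self.layer1(pooled)
        e7 = self.layer2(e3)
        e13 = self.layer3(e7)
        e16 = self.layer4(e13)
        return EncoderTaps(stem=stem, e3=e3, e7=e7, e13=e13, e16=e16)


def _translate_key(key: str) -> str:
    """Map standard ResNet34 parameter names onto this encoder's names."""
    out = key
    for i in (1, 2, 3, 4):
        prefix = f"layer{i}."
        if out.startswith(prefix):
            rest = out[len(prefix):]
            idx, _, tail = rest.partition(".")
            tail = tail.replace("downsample.0.", "downsample.mods.0.")
            tail = tail.replace("downsample.1.", "downsample.mods.1.")
            return f"layer{i}.mods.{idx}.{tail}"
    return out


def load_pretrained(encoder: ResNetEncoder, state_source) -> dict:
    """Copy matching ResNet34 weights into the encoder.

    ``state_source`` is a mapping from standard ResNet34 parameter names
    (``conv1.weight``, ``layer1.0.conv1.weight``, ...) to arrays, or a path
    to an ``.npz`` file holding such a mapping.  Requires the standard
    widths [64, 64, 128, 256, 512]; returns a report with ``loaded`` and
    ``skipped`` name lists.
    """
    if encoder.filters != RESNET34_FILTERS:
        raise IncompatibleWeightsError(
            f"pretrained ResNet34 weights need filters {list(RESNET34_FILTERS)} "
            f"(stem width 64), but the encoder stem is configured with width "
            f"{encoder.filters[0]} (filters {list(encoder.filters)})")
    if isinstance(state_source, (str, pathlib.Path)):
        path = pathlib.Path(state_source)
        if not path.exists():
            raise FileNotFoundError(f"pretrained weight file not found: {path}")
        with np.load(path) as npz:
            state = {k: npz[k] for k in npz.files}
    else:
        state = dict(state_source)

    own = dict(encoder.named_parameters())
    for name, mod in encoder.named_modules():
        if isinstance(mod, BatchNorm2d):
            own[name + ".running_mean"] = mod.running_mean
            own[name + ".running_var"] = mod.running_var

    loaded, skipped = [], []
    for key, value in state.items():
        target_name = _translate_key(key)
        target = own.get(target_name)
        if target is None:
            skipped.append(key)
            continue
        value = np.asarray(value)
        if isinstance(target, np.ndarray):
            if target.shape != value.shape:
                raise IncompatibleWeightsError(
                    f"shape mismatch for {key}: {target.shape} vs {value.shape}")
            target[...] = value
        else:
            if target.data.shape != value.shape:
                raise IncompatibleWeightsError(
                    f"shape mismatch for {key}: {target.data.shape} vs {value.shape}")
            target.data = value.astype(np.float32)
        loaded.append(key)
    return {"loaded": loaded, "skipped": skipped}
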