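"""Network configuration: the base-architecture hyperparameter space.

The search space mirrors the published ranges: input down-scaling 1/2/4
(extended to 8 for the coarse localizer which needs speed, not spatial
accuracy), 1-5 conv layers with 4-128 kernels of width 3-9 and optional 2x2
pooling, 0-2 hidden dense layers of 64-2048 neurons, dropout 0.3-0.7, and
one of three output heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

DOWNSCALE_CHOICES = (1, 2, 4)
DOWNSCALE_CHOICES_COARSE = (1, 2, 4, 8)
KERNEL_CHOICES = (4, 8, 16, 32, 64, 128)
WIDTH_CHOICES = (3, 4, 5, 6, 7, 8, 9)
N_CONV_CHOICES = (1, 2, 3, 4, 5)
N_DENSE_CHOICES = (0, 1, 2)
NEURON_CHOICES = (64, 128, 256, 512, 1024, 2048)
DROPOUT_CHOICES = (0.3, 0.4, 0.5, 0.6, 0.7)
HEADS = ("classifier", "regression", "center_of_mass")

MEMORY_LIMIT_BYTES = 11 * 1024 ** 3  # training-memory feasibility cap


class InvalidConfigError(ValueError):
    """Configuration outside the hyperparameter space or infeasible."""


@dataclass
class ConvSpec:
    n_kernels: int
    kernel_width: int
    pooling_2x2: bool = True
    batch_norm: bool = True


@dataclass
class NetConfig:
    """One point in the base-architecture hyperparameter space."""

    input_size: int                 # crop size in native px
    downscale: int = 1              # applied to the crop before the network
    conv_layers: List[ConvSpec] = field(default_factory=list)
    dense_layers: List[int] = field(default_factory=list)
    dropout: float = 0.5
    head: str = "center_of_mass"

    @property
    def net_input(self) -> int:
        return self.input_size // self.downscale

    def validate(self, strict_ranges: bool = True) -> None:
        if self.head not in HEADS:
            raise InvalidConfigError(f"unknown head {self.head!r}")
        if self.downscale not in DOWNSCALE_CHOICES_COARSE:
            raise InvalidConfigError(f"downscale {self.downscale} unsupported")
        if self.input_size % self.downscale:
            raise InvalidConfigError("downscale must divide the crop size")
        if not 1 <= len(self.conv_layers) <= 5:
            raise InvalidConfigError("need 1-5 conv layers")
        if len(self.dense_layers) > 2:
            raise InvalidConfigError("at most 2 hidden dense layers")
        if strict_ranges:
            for c in self.conv_layers:
                if c.n_kernels not in KERNEL_CHOICES:
                    raise InvalidConfigError(f"kernels {c.n_kernels} not in {KERNEL_CHOICES}")
                if c.kernel_width not in WIDTH_CHOICES:
                    raise InvalidConfigError(f"width {c.kernel_width} not in {WIDTH_CHOICES}")
            for n in self.dense_layers:
                if n not in NEURON_CHOICES:
                    raise InvalidConfigError(f"dense size {n} not in {NEURON_CHOICES}")
            if round(self.dropout, 1) not in DROPOUT_CHOICES:
                raise InvalidConfigError(f"dropout {self.dropout} not in {DROPOUT_CHOICES}")
        # spatial feasibility: every pooling stage must leave >= 1 px
        size = self.net_input
        if size < 1:
            raise InvalidConfigError("down-scaled input smaller than 1 px")
        for c in self.conv_layers:
            if c.pooling_2x2:
                if size < 2:
                    raise InvalidConfigError("pooling would reduce a map below 1 px")
                size //= 2
        if estimate_memory_bytes(self, batch_size=32) > MEMORY_LIMIT_BYTES:
            raise InvalidConfigError("configuration exceeds the training memory budget")

    def feature_maps(self) -> List[Tuple[int, int]]:
        """(channels, spatial size) after each conv stage, input included."""
        out = [(1, self.net_input)]
        size = self.net_input
        for c in self.conv_layers:
            if c.pooling_2x2:
                size //= 2
            out.append((c.n_kernels, size))
        return out

    def flat_features(self) -> int:
        ch, size = self.feature_maps()[-1]
        return ch * size * size

    def head_width(self) -> int:
        if self.head == "classifier":
            return 2
        if self.head == "regression":
            return 2
        return self.net_input * self.net_input


def estimate_memory_bytes(cfg: NetConfig, batch_size: int = 32) -> int:
    """Rough float32 training footprint: weights (x3 for Adam state) plus
    stored activations and im2col buffers for one batch."""
    maps = cfg.feature_maps()
    n_params = 0
    act = batch_size * maps[0][0] * maps[0][1] ** 2
    cols = 0
    cin, size = maps[0]
    for spec, (cout, out_size) in zip(cfg.conv_layers, maps[1:]):
        k = spec.kernel_width
        n_params += cout * cin * k * k + cout + (4 * cout if spec.batch_norm else 0)
        conv_size = size  # conv preserves size; pooling follows
        act += batch_size * cout * conv_size ** 2 * 3  # conv out, bn, relu
        cols = max(cols, batch_size * conv_size ** 2 * cin * k * k)
        act += batch_size * cout * out_size ** 2
        cin, size = cout, out_size
    feat = cin * size * size
    for n in cfg.dense_layers:
        n_params += feat * n + n
        act += batch_size * n * 2
        feat = n
    n_params += feat * cfg.head_width() + cfg.head_width()
    act += batch_size * cfg.head_width() * 2
    return 4 * (3 * n_params + act + cols)
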