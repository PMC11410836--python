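"""Encoder-decoder (U-Net style) heatmap-regression network.

Five resolution levels by default, with skip connections from each encoder
level to the matching decoder level.  Filter counts double per level from
``base_filters``; activations are ReLU inside and a sigmoid head bounds the
6-channel output to [0, 1] to match the heatmap targets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import List

import numpy as np

from ..errors import ConfigurationError
from .layers import (Adam, Conv2d, InstanceNorm, MaxPool2, ReLU, Sigmoid,
                     UpsampleNearest2)

Array = np.ndarray


@dataclass(frozen=True)
class ModelConfig:
    """Architecture parameters of the heatmap-regression network."""

    input_size: int = 512
    n_levels: int = 5
    out_channels: int = 6
    base_filters: int = 16
    convs_per_block: int = 2
    in_channels: int = 1
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 1 or self.base_filters < 1 or self.convs_per_block < 1:
            raise ConfigurationError("n_levels, base_filters, convs_per_block must be >= 1")
        if self.input_size % 2 ** (self.n_levels - 1) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by "
                f"2^{self.n_levels - 1}")

    @property
    def filters(self) -> List[int]:
        return [self.base_filters * 2 ** i for i in range(self.n_levels)]

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


class _ConvBlock:
    """``convs_per_block`` repetitions of Conv3x3 (+ InstanceNorm) + ReLU."""

    def __init__(self, c_in: int, c_out: int, n: int, rng: np.random.Generator,
                 normalize: bool = True):
        self.layers = []
        for i in range(n):
            self.layers.append(Conv2d(c_in if i == 0 else c_out, c_out, 3, rng))
            if normalize:
                self.layers.append(InstanceNorm(c_out))
            self.layers.append(ReLU())

    def forward(self, x: Array) -> Array:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: Array) -> Array:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class UNet:
    """The assembled network; see :class:`ModelConfig` for shape contracts."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = config.filters
        L = config.n_levels
        self.enc = [_ConvBlock(config.in_channels if i == 0 else f[i - 1],
                               f[i], config.convs_per_block, rng,
                               normalize=config.normalize)
                    for i in range(L)]
        self.pools = [MaxPool2() for _ in range(L - 1)]
        self.ups = [UpsampleNearest2() for _ in range(L - 1)]
        self.dec = [_ConvBlock(f[i] + f[i + 1], f[i], config.convs_per_block, rng,
                               normalize=config.normalize)
                    for i in range(L - 1)]
        self.head = Conv2d(f[0], config.out_channels, 1, rng)
        # Start the sigmoid head near-dark: heatmap targets are mostly
        # background, and a zero-bias start saturates the head toward
        # all-zero output with vanishing gradients before the line
        # structure can be learned.
        self.head.bias[:] = -2.0
        self.out_act = Sigmoid()

    # -- parameter plumbing -------------------------------------------------
    def _param_layers(self):
        layers = []
        for block in self.enc + self.dec:
            layers.extend(l for l in block.layers if getattr(l, "params", None))
        layers.append(self.head)
        return layers

    @property
    def params(self) -> List[Array]:
        return [p for c in self._param_layers() for p in c.params]

    @property
    def grads(self) -> List[Array]:
        return [g for c in self._param_layers() for g in c.grads]

    def get_weights(self) -> List[Array]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: List[Array]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params, self.grads, lr=lr)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: Array) -> Array:
        """(N, 1, S, S) -> (N, out_channels, S, S), values in [0, 1]."""
        if x.ndim != 4 or x.shape[2] != x.shape[3] or x.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, {self.config.input_size}, "
                f"{self.config.input_size}) input, got {x.shape}")
        skips = []
        L = self.config.n_levels
        for i in range(L):
            x = self.enc[i].forward(x)
            if i < L - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        self._skip_channels = [s.shape[1] for s in skips]
        for i in range(L - 2, -1, -1):
            up = self.ups[i].forward(x)
            x = self.dec[i].forward(np.concatenate([skips[i], up], axis=1))
        return self.out_act.forward(self.head.forward(x))

    def backward(self, dout: Array) -> None:
        d = self.head.backward(self.out_act.backward(dout))
        L = self.config.n_levels
        dskips = [None] * (L - 1)
        for i in range(L - 1):
            d = self.dec[i].backward(d)
            nskip = self._skip_channels[i]
            dskips[i] = d[:, :nskip]
            d = self.ups[i].backward(d[:, nskip:])
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc[i].backward(d)


def build_model(config: ModelConfig, seed: int = 0) -> UNet:
    """Construct a randomly initialized network for the given configuration."""
    return UNet(config, seed=seed)


def predict(network: UNet, image: Array):
    """Run one standardized grayscale image through the network.

    Returns a :class:`halluxmetry.heatmaps.HeatmapStack` (H x W x 6 in [0, 1]).
    """
    from ..heatmaps import HeatmapStack

    img = np.asarray(image, dtype=np.float64)
    s = network.config.input_size
    if img.shape != (s, s):
        raise ValueError(f"expected a {s}x{s} image, got {img.shape}")
    out = network.forward(img[None, None, :, :])[0]
    return HeatmapStack(np.clip(out.transpose(1, 2, 0), 0.0, 1.0))


def save_checkpoint(network: UNet, path) -> None:
    """Single-file checkpoint: weights + architecture config + config hash."""
    arrays = {f"w{i}": w for i, w in enumerate(network.params)}
    np.savez_compressed(
        path,
        config_json=np.array(json.dumps(asdict(network.config))),
        config_digest=np.array(network.config.digest()),
        **arrays,
    )


def load_checkpoint(path) -> UNet:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig(**json.loads(str(data["config_json"])))
        if str(data["config_digest"]) != config.digest():
            raise ConfigurationError("checkpoint config hash mismatch")
        net = UNet(config, seed=0)
        weights = [data[f"w{i}"] for i in range(len(net.params))]
        net.set_weights(weights)
    return net
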