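"""The two cascade networks: a separable-convolution denoiser and a U-Net
parameter mapper.

Denoiser: a DnCNN-style residual network whose layers factor a standard
convolution into a per-channel (depthwise) 3x3 spatial stage followed by a
pointwise (1x1) temporal stage mixing all resulting maps — the separable
structure treats the echo dimension the way hyperspectral restoration
networks treat spectral bands.  The network predicts the noise and subtracts
it from the input.

Mapper: a standard 2D U-Net with the echo images as input channels and two
output channels (S0, R2*).  The S0 channel passes through a softplus so it is
strictly positive; the R2* channel is linear during training (clamping to
>= 0 happens at inference), scaled by ``r2_output_scale`` into s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    DTYPE,
    DepthwiseConv2d,
    Layer,
    MaxPool2d,
    ReLU,
    Sequential,
    Upsample2x,
    count_parameters,
    sigmoid,
    softplus,
)

__all__ = [
    "DenoiserConfig",
    "MapperConfig",
    "SeparableDenoiser",
    "UNetMapper",
    "build_denoiser",
    "build_mapper",
    "count_parameters",
]


@dataclass(frozen=True)
class DenoiserConfig:
    n_echoes: int = 12
    n_layers: int = 8
    spatial_kernels_per_channel: int = 10
    temporal_out_channels: int = 40
    residual: bool = True
    batch_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("denoiser needs at least 2 layers")


@dataclass(frozen=True)
class MapperConfig:
    in_channels: int = 12
    depth: int = 4
    base_width: int = 32
    batch_norm: bool = True
    upsampling: str = "transposed"  # or "nearest+conv"
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.upsampling not in ("transposed", "nearest+conv"):
            raise ValueError("upsampling must be 'transposed' or 'nearest+conv'")

    @property
    def out_channels(self) -> int:
        return 2


class SeparableDenoiser(Layer):
    """Residual stack of depthwise-then-pointwise convolution layers."""

    def __init__(self, cfg: DenoiserConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        mult = cfg.spatial_kernels_per_channel
        mid = cfg.temporal_out_channels
        layers: list[Layer] = []
        cin = cfg.n_echoes
        for i in range(cfg.n_layers - 1):
            layers.append(DepthwiseConv2d(cin, mult, rng=rng))
            layers.append(Conv2d(cin * mult, mid, k=1, rng=rng))
            if cfg.batch_norm:
                layers.append(BatchNorm2d(mid))
            layers.append(ReLU())
            cin = mid
        # Final separable layer restores the echo count, no BN / activation.
        layers.append(DepthwiseConv2d(cin, mult, rng=rng))
        final = Conv2d(cin * mult, cfg.n_echoes, k=1, rng=rng)
        # start the residual branch near zero so the network begins close to
        # the identity (predicting zero noise)
        final.w.data *= DTYPE(0.01)
        layers.append(final)
        self.body = Sequential(*layers)

    def params(self):
        return self.body.params()

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.body.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:
        noise = self.body.forward(x)
        return x - noise if self.cfg.residual else noise

    def backward(self, g: np.ndarray) -> np.ndarray:
        dnoise = self.body.backward(-g if self.cfg.residual else g)
        return g + dnoise if self.cfg.residual else dnoise


class _UpBlock(Layer):
    """2x upsampling stage: transposed conv or nearest + 3x3 conv."""

    def __init__(self, cin: int, cout: int, mode: str, rng):
        if mode == "transposed":
            self.op = Sequential(ConvTranspose2d(cin, cout, rng=rng))
        else:
            self.op = Sequential(Upsample2x(), Conv2d(cin, cout, k=3, rng=rng))

    def params(self):
        return self.op.params()

    def set_training(self, flag):
        self.op.set_training(flag)

    def forward(self, x):
        return self.op.forward(x)

    def backward(self, g):
        return self.op.backward(g)


def _conv_block(cin: int, cout: int, bn: bool, rng) -> Sequential:
    layers: list[Layer] = [Conv2d(cin, cout, k=3, rng=rng)]
    if bn:
        layers.append(BatchNorm2d(cout))
    layers += [ReLU(), Conv2d(cout, cout, k=3, rng=rng)]
    if bn:
        layers.append(BatchNorm2d(cout))
    layers.append(ReLU())
    return Sequential(*layers)


class UNetMapper(Layer):
    """Symmetric encoder/decoder with skip concatenations, 2-channel head."""

    def __init__(self, cfg: MapperConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = [cfg.base_width * 2**i for i in range(cfg.depth)]
        self.enc = []
        cin = cfg.in_channels
        for w in widths:
            self.enc.append(_conv_block(cin, w, cfg.batch_norm, rng))
            cin = w
        self.pools = [MaxPool2d() for _ in widths]
        self.bottleneck = _conv_block(widths[-1], widths[-1] * 2, cfg.batch_norm, rng)
        self.ups = []
        self.dec = []
        cin = widths[-1] * 2
        for w in reversed(widths):
            self.ups.append(_UpBlock(cin, w, cfg.upsampling, rng))
            self.dec.append(_conv_block(2 * w, w, cfg.batch_norm, rng))
            cin = w
        self.head = Conv2d(widths[0], cfg.out_channels, k=1, rng=rng)
        # small head weights and mid-range biases keep the decay exponent
        # well-conditioned at the start of training (S0 ~ softplus(0.54) ~ 1
        # in normalized units, R2* head ~ 0.5 of its output scale)
        self.head.w.data *= DTYPE(0.01)
        self.head.b.data[:] = np.array([0.54, 0.5], dtype=DTYPE)[: cfg.out_channels]
        self._modules: list[Layer] = (
            self.enc + self.pools + [self.bottleneck] + self.ups + self.dec + [self.head]
        )

    def params(self):
        return [p for m in self._modules for p in m.params()]

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for m in self._modules:
            m.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[2:]
        if h % 2**self.cfg.depth or w % 2**self.cfg.depth:
            raise ValueError(
                f"spatial dims {(h, w)} must be divisible by {2 ** self.cfg.depth}"
            )
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x)
        u = self.head.forward(x)
        # softplus on the S0 channel; R2* channel linear.
        self._u0 = u[:, 0]
        out = np.empty_like(u)
        out[:, 0] = softplus(self._u0)
        out[:, 1:] = u[:, 1:]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        gu = g.copy()
        gu[:, 0] = g[:, 0] * sigmoid(self._u0)
        x = self.head.backward(gu)
        gskips = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            x = dec.backward(x)
            w = x.shape[1] // 2
            gskips.append(x[:, :w])
            x = up.backward(x[:, w:])
        x = self.bottleneck.backward(x)
        for block, pool, gskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(gskips)
        ):
            x = pool.backward(x)
            x = block.backward(x + gskip)
        return x


def build_denoiser(cfg: DenoiserConfig | None = None) -> SeparableDenoiser:
    return SeparableDenoiser(cfg or DenoiserConfig())


def build_mapper(cfg: MapperConfig | None = None) -> UNetMapper:
    return UNetMapper(cfg or MapperConfig())


def get_state(net: Layer) -> list[np.ndarray]:
    """Copies of all trainable arrays plus batch-norm running stats."""
    state = [p.data.copy() for p in net.params()]
    state += [s.copy() for s in _running_stats(net)]
    return state


def set_state(net: Layer, state: list[np.ndarray]) -> None:
    params = net.params()
    stats = _running_stats(net)
    if len(state) != len(params) + len(stats):
        raise ValueError("state length mismatch")
    for p, a in zip(params, state[: len(params)]):
        p.data[...] = a
    for s, a in zip(stats, state[len(params):]):
        s[...] = a


def _running_stats(net: Layer) -> list[np.ndarray]:
    from .core import iter_batchnorms

    out = []
    for bn in iter_batchnorms(net):
        out.append(bn.running_mean)
        out.append(bn.running_var)
    return out
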