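"""RedSCAN: residual dense spatial-channel attention network.

The de-aliasing backbone used inside each cascade block.  Fully
convolutional, no downsampling, single-channel in and out:

* initial feature extraction (IFE): two 3x3 convolutions producing
  ``F_-1`` (kept for the global residual) and ``F_0``;
* ``n_blocks`` residual dense spatial-channel attention blocks (RedSCAB),
  each with ``n_dense_convs`` densely connected 3x3 convolutions
  (leaky-ReLU), a 1x1 local feature fusion over the block input plus all
  dense outputs, a spatial-channel attention stage, and a local residual
  connection;
* global feature fusion (1x1 then 3x3 convolution over the concatenated
  block outputs), a global residual add of ``F_-1``, and a final 3x3
  convolution producing the unregularized output image.

Channel attention squeezes spatially (global average pool, two fully
connected layers C -> C/r -> C, ReLU then sigmoid) and rescales channels;
spatial attention squeezes channel-wise (1x1 convolution to one map,
sigmoid) and rescales locations.  The two branch outputs are summed.  When
an attention branch is disabled it is removed from the sum; with both
disabled the fused features are the unattended LFF output, so the block
reduces to a plain residual dense block.

Weights use Kaiming fan-in initialization from a seeded generator so
networks are reproducible; biases start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .errors import ContractError


@dataclass
class RedSCANConfig:
    """Architecture hyperparameters of the backbone."""

    n_features: int = 32        # C, channels of the IFE output
    n_blocks: int = 5           # number of RedSCABs
    n_dense_convs: int = 4      # dense convolutions per block
    growth: int = 32            # output channels of each dense convolution
    use_channel_attention: bool = True
    use_spatial_attention: bool = True
    leaky_slope: float = 0.01
    ca_reduction: int = 2       # channel-attention bottleneck divisor
    seed: int = 0               # weight-init seed

    def __post_init__(self) -> None:
        for v in (self.n_features, self.n_blocks, self.n_dense_convs, self.growth,
                  self.ca_reduction):
            if v < 1:
                raise ContractError("all architecture counts must be >= 1")
        if self.n_features % self.ca_reduction:
            raise ContractError("n_features must be divisible by ca_reduction")


class Module:
    """Tiny module base: recursive parameter collection."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def zero_(self) -> None:
        for p in self.parameters():
            p.data[...] = 0.0


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.pad = (k - 1) // 2
        self.w = Parameter(_kaiming(rng, (cout, cin, k, k), cin * k * k))
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, self.pad)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Parameter(_kaiming(rng, (cout, cin), cin))
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.w, self.b)


class ChannelAttention(Module):
    """Squeeze spatially, excite channel-wise: f_z * sigmoid(FC2(relu(FC1(mean_z))))."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        self.fc1 = Linear(channels, channels // reduction, rng)
        self.fc2 = Linear(channels // reduction, channels, rng)

    def calibration(self, f: Tensor) -> Tensor:
        v = ad.global_avg_pool(f)
        return ad.sigmoid(self.fc2(ad.relu(self.fc1(v))))

    def __call__(self, f: Tensor) -> Tensor:
        vhat = self.calibration(f)
        n, c = vhat.shape
        return ad.mul(f, ad.reshape(vhat, (n, c, 1, 1)))


class SpatialAttention(Module):
    """Squeeze channel-wise with a 1x1 convolution, excite per location."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv = Conv2d(channels, 1, 1, rng)

    def calibration(self, f: Tensor) -> Tensor:
        return ad.sigmoid(self.conv(f))

    def __call__(self, f: Tensor) -> Tensor:
        return ad.mul(f, self.calibration(f))


class RedSCAB(Module):
    """One residual dense spatial-channel attention block."""

    def __init__(self, config: RedSCANConfig, rng: np.random.Generator):
        c, g = config.n_features, config.growth
        self.slope = config.leaky_slope
        self.use_ca = config.use_channel_attention
        self.use_sa = config.use_spatial_attention
        self.dense = [
            Conv2d(c + t * g, g, 3, rng) for t in range(config.n_dense_convs)
        ]
        self.lff = Conv2d(c + config.n_dense_convs * g, c, 1, rng)
        self.ca = ChannelAttention(c, config.ca_reduction, rng) if self.use_ca else None
        self.sa = SpatialAttention(c, rng) if self.use_sa else None

    def __call__(self, f_prev: Tensor) -> Tensor:
        feats = [f_prev]
        for conv in self.dense:
            feats.append(ad.leaky_relu(conv(ad.concat(feats)), self.slope))
        f_lf = self.lff(ad.concat(feats))
        branches = []
        if self.ca is not None:
            branches.append(self.ca(f_lf))
        if self.sa is not None:
            branches.append(self.sa(f_lf))
        if branches:
            f_sca = branches[0]
            for b in branches[1:]:
                f_sca = ad.add(f_sca, b)
        else:
            f_sca = f_lf
        return ad.add(f_sca, f_prev)


class RedSCAN(Module):
    """The full backbone; input and output are (N, 1, H, W)."""

    def __init__(self, config: RedSCANConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.n_features
        self.ife1 = Conv2d(1, c, 3, rng)
        self.ife2 = Conv2d(c, c, 3, rng)
        self.blocks = [RedSCAB(config, rng) for _ in range(config.n_blocks)]
        self.gff1 = Conv2d(c * config.n_blocks, c, 1, rng)
        self.gff2 = Conv2d(c, c, 3, rng)
        self.final = Conv2d(c, 1, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        f_m1 = self.ife1(x)
        f = self.ife2(f_m1)
        locals_: list[Tensor] = []
        for block in self.blocks:
            f = block(f)
            locals_.append(f)
        f_gf = self.gff2(self.gff1(ad.concat(locals_)))
        return self.final(ad.add(f_gf, f_m1))

    def forward_array(self, x: np.ndarray) -> np.ndarray:
        """Inference on a raw (N, 1, H, W) or (H, W) array."""
        arr = np.asarray(x, float)
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[None, None]
        out = self(Tensor(arr)).data
        return out[0, 0] if squeeze else out

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ContractError("checkpoint does not match architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ContractError("checkpoint parameter shape mismatch")
            p.data[...] = a


def build_redscan(config: RedSCANConfig | None = None) -> RedSCAN:
    """Instantiate the backbone with reproducible initialization."""
    return RedSCAN(config or RedSCANConfig())


def count_parameters(network: Module) -> int:
    """Total learnable scalars (weights + biases)."""
    return int(sum(p.data.size for p in network.parameters()))


def redscab_forward(f_prev: np.ndarray, block: RedSCAB) -> np.ndarray:
    """Apply one block to a raw (C, H, W) or (N, C, H, W) feature grid."""
    arr = np.asarray(f_prev, float)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    out = block(Tensor(arr)).data
    return out[0] if squeeze else out


def channel_attention(f: np.ndarray, module: ChannelAttention) -> np.ndarray:
    """Apply channel attention to a raw (C, H, W) or (N, C, H, W) grid."""
    arr = np.asarray(f, float)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    out = module(Tensor(arr)).data
    return out[0] if squeeze else out


def spatial_attention(f: np.ndarray, module: SpatialAttention) -> np.ndarray:
    """Apply spatial attention to a raw (C, H, W) or (N, C, H, W) grid."""
    arr = np.asarray(f, float)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    out = module(Tensor(arr)).data
    return out[0] if squeeze else out


def sca_fuse(f_ca: np.ndarray, f_sa: np.ndarray) -> np.ndarray:
    """Elementwise sum of the two attention branch outputs."""
    f_ca, f_sa = np.asarray(f_ca, float), np.asarray(f_sa, float)
    if f_ca.shape != f_sa.shape:
        raise ContractError("attention branch shapes differ")
    return f_ca + f_sa
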