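"""SE-augmented encoder-decoder for pixelwise sFAZ classification.

The architecture maps a normalized grayscale image to a same-size map of
sFAZ probabilities.  The encoder is two stem Conv-BN-ReLU blocks (C1-C2)
followed by five pooling blocks (P1-P5), each a Conv-BN-ReLU block, a
squeeze-and-excitation (SE) block, and a 2x2 max pool; at the study-scale
input of 704 x 704 the bottleneck is 22 x 22.  The decoder mirrors it with
five upsampling blocks (U1-U5) — bilinear 2x upsampling, concatenation
with the matching encoder skip (the SE output before pooling), Conv-BN-ReLU
and SE — and a reconstruction head of one convolution plus a sigmoid.

A Conv-BN-ReLU block is two successive convolution -> batch-normalization
-> ReLU stages with same-size padding.  The SE block global-average-pools
each channel, passes the channel vector through a bottleneck pair of dense
layers (ReLU then sigmoid), and rescales each channel by the resulting
weight in (0, 1).

Everything runs on the package's own numpy reverse-mode autodiff engine;
parameters use He-uniform initialisation, seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = [
    "NetworkConfig",
    "ConvBNReLU",
    "SEBlock",
    "PoolingBlock",
    "UpsamplingBlock",
    "SegmentationNetwork",
    "shape_trace",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``channel_schedule`` lists the feature dimension after the stem and
    after each pooling block (length ``n_pool + 1``).  ``input_size`` must
    be divisible by ``2**n_pool``.
    """

    input_size: int = 704
    n_pool: int = 5
    channel_schedule: tuple = (32, 64, 128, 256, 512, 512)
    se_reduction: int = 16
    kernel_size: int = 3

    def __post_init__(self):
        if self.input_size % (2 ** self.n_pool) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.n_pool}"
            )
        if len(self.channel_schedule) != self.n_pool + 1:
            raise ValueError("channel_schedule must have n_pool + 1 entries")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be positive")

    @staticmethod
    def scaled_down() -> "NetworkConfig":
        """Reduced configuration for CPU-scale experiments (128 x 128 input)."""
        return NetworkConfig(input_size=128, channel_schedule=(8, 16, 32, 32, 32, 32), se_reduction=4)


def _he_uniform(rng, shape, fan_in):
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class _Layer:
    def parameters(self):
        return []

    def train(self, mode: bool = True):
        for p in self.__dict__.values():
            if isinstance(p, _Layer):
                p.train(mode)


class Conv2d(_Layer):
    def __init__(self, in_ch, out_ch, k, rng):
        fan_in = in_ch * k * k
        self.weight = Parameter(_he_uniform(rng, (out_ch, in_ch, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)

    def parameters(self):
        return [self.weight, self.bias]


class BatchNorm2d(_Layer):
    """Per-channel standardization with learned scale/shift and running stats."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        self.gamma = Parameter(np.ones((1, channels, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1, 1), dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def train(self, mode: bool = True):
        self.training = mode

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ad.batchnorm(x, self.gamma, self.beta, eps=self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
            return out
        xn = (x - Tensor(self.running_mean)) * Tensor(
            1.0 / np.sqrt(self.running_var + self.eps)
        )
        return self.gamma * xn + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class ConvBNReLU(_Layer):
    """Two successive convolution -> batch-norm -> ReLU stages."""

    def __init__(self, in_ch, out_ch, k, rng):
        self.conv1 = Conv2d(in_ch, out_ch, k, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, k, rng)
        self.bn2 = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.relu(self.bn1(self.conv1(x)))
        return ad.relu(self.bn2(self.conv2(x)))

    def parameters(self):
        return (self.conv1.parameters() + self.bn1.parameters()
                + self.conv2.parameters() + self.bn2.parameters())


class SEBlock(_Layer):
    """Squeeze-and-excitation channel attention.

    Global average pooling -> dense (d -> d/r, ReLU) -> dense (d/r -> d,
    sigmoid) -> per-channel rescaling.  Each channel weight lies strictly in
    (0, 1).
    """

    def __init__(self, channels, reduction, rng):
        if channels < reduction:
            raise ValueError("SE reduction exceeds the channel count")
        hidden = max(1, channels // reduction)
        self.w1 = Parameter(_he_uniform(rng, (channels, hidden), channels))
        self.b1 = Parameter(np.zeros(hidden, dtype=np.float32))
        self.w2 = Parameter(_he_uniform(rng, (hidden, channels), hidden))
        self.b2 = Parameter(np.zeros(channels, dtype=np.float32))
        self.channels = channels

    def channel_weights(self, x: Tensor) -> Tensor:
        squeezed = x.mean(axis=(2, 3)).reshape(-1, self.channels)
        hidden = ad.relu(squeezed @ self.w1 + self.b1)
        return ad.sigmoid(hidden @ self.w2 + self.b2)

    def __call__(self, x: Tensor) -> Tensor:
        s = self.channel_weights(x)
        n = x.shape[0]
        return x * s.reshape(n, self.channels, 1, 1)

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]


class PoolingBlock(_Layer):
    """Conv-BN-ReLU + SE, then 2x2 max pooling; also exposes the skip."""

    def __init__(self, in_ch, out_ch, k, reduction, rng):
        self.features = ConvBNReLU(in_ch, out_ch, k, rng)
        self.se = SEBlock(out_ch, reduction, rng)

    def __call__(self, x: Tensor):
        h, w = x.shape[2], x.shape[3]
        if h % 2 or w % 2:
            raise ValueError("pooling block requires even spatial dimensions")
        skip = self.se(self.features(x))
        return ad.maxpool2(skip), skip

    def parameters(self):
        return self.features.parameters() + self.se.parameters()


class UpsamplingBlock(_Layer):
    """Bilinear 2x upsample, concatenate the encoder skip, Conv-BN-ReLU + SE."""

    def __init__(self, in_ch, skip_ch, out_ch, k, reduction, rng):
        self.features = ConvBNReLU(in_ch + skip_ch, out_ch, k, rng)
        self.se = SEBlock(out_ch, reduction, rng)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        if (skip.shape[2], skip.shape[3]) != (2 * x.shape[2], 2 * x.shape[3]):
            raise ValueError("skip spatial size must be twice the input's")
        up = ad.upsample_bilinear2(x)
        fused = ad.concat([up, skip], axis=1)
        return self.se(self.features(fused))

    def parameters(self):
        return self.features.parameters() + self.se.parameters()


class SegmentationNetwork(_Layer):
    """The full encoder-decoder; input and output are the same square size."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cs = config.channel_schedule
        k, r = config.kernel_size, config.se_reduction
        self.stem1 = ConvBNReLU(1, cs[0], k, rng)
        self.stem2 = ConvBNReLU(cs[0], cs[0], k, rng)
        self.pool_blocks = [
            PoolingBlock(cs[i], cs[i + 1], k, r, rng) for i in range(config.n_pool)
        ]
        # decoder runs deepest-first: U1 consumes the P5 skip, U5 the P1 skip
        self.up_blocks = [
            UpsamplingBlock(cs[i + 1], cs[i + 1], cs[i], k, r, rng)
            for i in reversed(range(config.n_pool))
        ]
        self.head = Conv2d(cs[0], 1, 1, rng)
        # start the head at the foreground prior log-odds (the sFAZ covers a
        # few percent of the field) so early training is not spent
        # unlearning a 50% prior
        self.head.bias.data[:] = -3.0

    def train(self, mode: bool = True):
        self.stem1.train(mode)
        self.stem2.train(mode)
        for b in self.pool_blocks + self.up_blocks:
            b.train(mode)

    def forward_logits(self, x) -> Tensor:
        """Logit map for a batch; ``x`` is (N, 1, H, W) normalized input."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"input must be {self.config.input_size}x{self.config.input_size}"
            )
        h = self.stem2(self.stem1(x))
        skips = []
        for block in self.pool_blocks:
            h, skip = block(h)
            skips.append(skip)
        for block, skip in zip(self.up_blocks, reversed(skips)):
            h = block(h, skip)
        return self.head(h)

    def forward(self, x) -> Tensor:
        """Per-pixel sFAZ probability map, values strictly in (0, 1)."""
        return ad.sigmoid(self.forward_logits(x))

    def predict_proba(self, images: np.ndarray, batch_size: int = 4) -> np.ndarray:
        """Evaluation-mode probabilities for (N, H, W) normalized images."""
        self.train(False)
        imgs = np.asarray(images, dtype=np.float32)
        if imgs.ndim == 2:
            imgs = imgs[None]
        out = []
        with ad.no_grad():
            for i in range(0, len(imgs), batch_size):
                batch = imgs[i:i + batch_size, None, :, :]
                out.append(self.forward(batch).data[:, 0])
        self.train(True)
        return np.concatenate(out, axis=0)

    def parameters(self):
        params = self.stem1.parameters() + self.stem2.parameters()
        for b in self.pool_blocks + self.up_blocks:
            params += b.parameters()
        return params + self.head.parameters()

    # -- checkpoint plumbing ------------------------------------------
    def state_arrays(self):
        """Flat dict of every parameter and batch-norm running statistic."""
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data
        for j, bn in enumerate(self._batchnorms()):
            state[f"bn_{j}_mean"] = bn.running_mean
            state[f"bn_{j}_var"] = bn.running_var
        return state

    def load_state_arrays(self, state):
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"param_{i}"], dtype=np.float32)
        for j, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(state[f"bn_{j}_mean"], dtype=np.float32)
            bn.running_var = np.asarray(state[f"bn_{j}_var"], dtype=np.float32)

    def _batchnorms(self):
        bns = []
        for blk in [self.stem1, self.stem2] + [b.features for b in self.pool_blocks] + [
            b.features for b in self.up_blocks
        ]:
            bns += [blk.bn1, blk.bn2]
        return bns


def shape_trace(config: NetworkConfig) -> list:
    """(block_name, h, w, d) for every block output, without allocating weights.

    The encoder halves the spatial size ``n_pool`` times (704 -> 352 -> 176
    -> 88 -> 44 -> 22 at study scale) and the decoder doubles it back.
    """
    cs = config.channel_schedule
    s = config.input_size
    trace = [("C1", s, s, cs[0]), ("C2", s, s, cs[0])]
    for i in range(config.n_pool):
        s //= 2
        trace.append((f"P{i + 1}", s, s, cs[i + 1]))
    for i in range(config.n_pool):
        s *= 2
        trace.append((f"U{i + 1}", s, s, cs[config.n_pool - 1 - i]))
    trace.append(("R1", s, s, 1))
    return trace


def save_checkpoint(path, network: SegmentationNetwork, meta: dict | None = None):
    """Serialize parameters, running stats, config and metadata to one .npz."""
    cfg = {
        "input_size": network.config.input_size,
        "n_pool": network.config.n_pool,
        "channel_schedule": list(network.config.channel_schedule),
        "se_reduction": network.config.se_reduction,
        "kernel_size": network.config.kernel_size,
    }
    header = json.dumps({"config": cfg, "meta": meta or {}})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **network.state_arrays())


def load_checkpoint(path):
    """Rebuild a network (and its metadata) from a checkpoint file."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        cfg = header["config"]
        net = SegmentationNetwork(
            NetworkConfig(
                input_size=cfg["input_size"],
                n_pool=cfg["n_pool"],
                channel_schedule=tuple(cfg["channel_schedule"]),
                se_reduction=cfg["se_reduction"],
                kernel_size=cfg["kernel_size"],
            )
        )
        net.load_state_arrays({k: data[k] for k in data.files if k != "__header__"})
    return net, header["meta"]
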