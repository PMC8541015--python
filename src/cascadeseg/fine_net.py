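"""Stage-2 fine segmentation: multi-resolution dense-ASPP with channel attention.

The coarse probability map is fused with the (min-max normalised) input image
by addition, the fused map is presented at three resolutions (full, 1/2, 1/4
— 512/256/128 at native CT size), and each resolution branch runs a stem
convolution, a densely connected atrous-spatial-pyramid-pooling block and a
multi-layered channel-attention module.  Branch features are bilinearly
up-sampled to full resolution, fused by addition, and a final convolution +
softmax yields the refined three-class probability map.

The dense-ASPP block chains dilated 3x3 convolutions whose inputs are the
concatenation of the block input and every previous layer's output; dilation
rates stay below 24, past which dilated kernels sample too sparsely to be
effective.  Channel attention forms three branches with different kernel
sizes; each pools its features globally (max and average), passes both
descriptors through a shared length-K convolution along the channel axis,
sums them, and squashes with a sigmoid into per-channel weights that
recalibrate the branch before the branches are summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

MAX_DILATION = 24  # dilated kernels degrade beyond this rate


@dataclass(frozen=True)
class ADenseConfig:
    in_channels: int = 1
    width: int = 32
    growth_rate: int = 32
    dilation_rates: tuple[int, ...] = (1, 3, 6, 12)
    attention_kernel: int = 3
    branch_kernels: tuple[int, int, int] = (1, 3, 5)
    resolutions: tuple[int, ...] = (1, 2, 4)
    n_classes: int = 3
    use_attention: bool = True

    def __post_init__(self):
        for r in self.dilation_rates:
            if r < 1:
                raise ValueError("dilation rates must be >= 1")
            if r >= MAX_DILATION:
                raise ValueError(
                    f"dilation rate {r} >= {MAX_DILATION}: dilated convolution "
                    "samples too sparsely to be effective at such rates")
        if self.attention_kernel % 2 == 0:
            raise ValueError("attention kernel K must be odd")
        if self.width < self.attention_kernel:
            raise ValueError("channel count must be >= attention kernel K")

    @property
    def n_layers(self) -> int:
        return len(self.dilation_rates)


#: reduced profile for CPU-scale experiments and tests
CPU_TEST_ADENSE = ADenseConfig(width=8, growth_rate=8)


def fuse_coarse(prob: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Fuse the coarse prior with the image by addition (single channel).

    The image is min-max normalised to [0, 1]; the summed foreground
    probability (liver + tumor) is added elementwise.
    """
    prob = np.asarray(prob, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if prob.ndim != 3 or prob.shape[0] < 3:
        raise ValueError("prob must be (n_classes, H, W)")
    if prob.shape[1:] != image.shape:
        raise ValueError(f"prob {prob.shape[1:]} and image {image.shape} differ")
    lo, hi = image.min(), image.max()
    norm = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    return (norm + prob[1] + prob[2]).astype(np.float32)


def build_multires_inputs(fused: np.ndarray,
                          factors: tuple[int, ...] = (1, 2, 4)) -> list[np.ndarray]:
    """Bilinear pyramid of the fused input; factor 1 is the input itself."""
    fused = np.asarray(fused, dtype=np.float32)
    squeeze = fused.ndim == 2
    if squeeze:
        fused = fused[None, None]
    elif fused.ndim == 3:
        fused = fused[:, None]
    n, c, h, w = fused.shape
    fmax = max(factors)
    if h % fmax or w % fmax:
        raise ValueError(f"side {h}x{w} not divisible by max factor {fmax}")
    out = []
    for f in factors:
        if f == 1:
            branch = fused
        else:
            branch = nn.bilinear_resize(Tensor(fused), h // f, w // f).data
        out.append(branch[0, 0] if squeeze else branch)
    return out


class ADenseBlock(nn.Module):
    """Dense connectivity over dilated convolutions (dense ASPP).

    Layer i receives C + (i-1)*growth_rate channels — the block input
    concatenated with all previous layers' outputs — and emits growth_rate
    channels through a dilated 3x3 convolution; a 1x1 projection returns the
    full concatenation to C channels.
    """

    def __init__(self, channels: int, config: ADenseConfig, rng):
        self.channels = channels
        self.layers = []
        in_ch = channels
        for rate in config.dilation_rates:
            self.layers.append(nn.ConvRelu(in_ch, config.growth_rate, 3, rng,
                                           dilation=rate))
            in_ch += config.growth_rate
        self.project = nn.Conv2d(in_ch, channels, 1, rng)

    def layer_input_channels(self) -> list[int]:
        return [layer.conv.in_ch for layer in self.layers]

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for layer in self.layers:
            h = feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)
            feats.append(layer(h))
        return self.project(nn.concat(feats, axis=1))


class ChannelAttention(nn.Module):
    """Multi-layered channel attention over three convolution branches."""

    def __init__(self, channels: int, config: ADenseConfig, rng):
        if channels < config.attention_kernel:
            raise ValueError("channel count must be >= attention kernel K")
        self.branches = [nn.Conv2d(channels, channels, k, rng)
                         for k in config.branch_kernels]
        # one shared channel-axis transform per branch (shared between the
        # max-pool and average-pool descriptors of that branch)
        self.shared = [nn.ChannelConv1d(config.attention_kernel, rng)
                       for _ in config.branch_kernels]

    def branch_weights(self, x: Tensor) -> list[Tensor]:
        """Per-branch per-channel sigmoid weights, each (N, C)."""
        weights = []
        for conv, shared in zip(self.branches, self.shared):
            f = conv(x)
            desc = nn.add(shared(nn.global_max_pool(f)),
                          shared(nn.global_avg_pool(f)))
            weights.append(nn.sigmoid(desc))
        return weights

    def forward(self, x: Tensor) -> Tensor:
        out = None
        for conv, shared in zip(self.branches, self.shared):
            f = conv(x)
            desc = nn.add(shared(nn.global_max_pool(f)),
                          shared(nn.global_avg_pool(f)))
            w = nn.sigmoid(desc)
            calibrated = nn.mul(f, _expand_nc(w))
            out = calibrated if out is None else nn.add(out, calibrated)
        return out


# Tensor lacks a reshape op; channel weights only need a broadcastable view.
def _expand_nc(w: Tensor) -> Tensor:
    n, c = w.shape
    out = nn.Tensor(w.data.reshape(n, c, 1, 1))

    def bwd(g):
        if w.requires_grad:
            if w.grad is None:
                w.grad = g.reshape(n, c).copy()
            else:
                w.grad += g.reshape(n, c)

    if w.requires_grad:
        out.requires_grad = True
        out._parents = (w,)
        out._backward = bwd
    return out


class _Branch(nn.Module):
    def __init__(self, config: ADenseConfig, rng):
        self.stem = nn.ConvRelu(config.in_channels, config.width, 3, rng)
        self.adense = ADenseBlock(config.width, config, rng)
        self.attention = (ChannelAttention(config.width, config, rng)
                          if config.use_attention else None)

    def forward(self, x: Tensor) -> Tensor:
        h = self.adense(self.stem(x))
        if self.attention is not None:
            h = self.attention(h)
        return h


class ADenseNet(nn.Module):
    """The full stage-2 network over the configured resolution branches."""

    def __init__(self, config: ADenseConfig, rng: np.random.Generator):
        self.config = config
        self.branch_nets = [_Branch(config, rng) for _ in config.resolutions]
        self.head = nn.Conv2d(config.width, config.n_classes, 3, rng)

    def forward(self, branch_inputs: list[Tensor]) -> Tensor:
        cfg = self.config
        if len(branch_inputs) != len(cfg.resolutions):
            raise ValueError(f"expected {len(cfg.resolutions)} branch inputs, "
                             f"got {len(branch_inputs)}")
        full_h, full_w = branch_inputs[0].shape[-2:]
        fused = None
        for net, x in zip(self.branch_nets, branch_inputs):
            h = net(x)
            if h.shape[-2:] != (full_h, full_w):
                h = nn.bilinear_resize(h, full_h, full_w)
            fused = h if fused is None else nn.add(fused, h)
        return self.head(fused)


def build_adensenet(config: ADenseConfig = ADenseConfig(),
                    seed: int | np.random.Generator = 0) -> ADenseNet:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ADenseNet(config, rng)


def fine_forward(net: ADenseNet, branch_inputs: list[np.ndarray]) -> np.ndarray:
    """Refined probability map(s) from multi-resolution fused inputs."""
    squeeze = np.asarray(branch_inputs[0]).ndim == 2
    tensors = []
    for b in branch_inputs:
        b = np.asarray(b, dtype=np.float32)
        if b.ndim == 2:
            b = b[None, None]
        elif b.ndim == 3:
            b = b[:, None]
        tensors.append(Tensor(b))
    logits = net(tensors)
    probs = nn.softmax_np(logits.data, axis=1)
    return probs[0] if squeeze else probs
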