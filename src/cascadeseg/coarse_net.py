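"""Stage-1 coarse segmentation: a U-Net encoder-decoder.

The contracting path applies two 3x3 convolutions + ReLU per level and 2x2
max pooling with channel doubling; the expanding path mirrors it with 2x2
transposed convolutions (halving channels), skip concatenation, and two 3x3
convolutions; a final 1x1 convolution maps to the three classes.  With the
default depth 4 / base width 64 this yields the classic 23 convolutional
layers.  All 3x3 convolutions use "same" padding so a 512x512 input yields a
512x512 probability map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 1
    base_width: int = 64
    depth: int = 4
    n_classes: int = 3

    def __post_init__(self):
        if self.depth < 1 or self.base_width < 1:
            raise ValueError("depth and base_width must be >= 1")


#: reduced profile for CPU-scale experiments and tests
CPU_TEST_UNET = UNetConfig(base_width=8, depth=3)


class _DoubleConv(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng):
        self.c1 = nn.ConvRelu(in_ch, out_ch, 3, rng)
        self.c2 = nn.ConvRelu(out_ch, out_ch, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x))


class UNet(nn.Module):
    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        self.config = config
        w = config.base_width
        self.down = []
        in_ch = config.in_channels
        for d in range(config.depth):
            self.down.append(_DoubleConv(in_ch, w * 2 ** d, rng))
            in_ch = w * 2 ** d
        self.bottleneck = _DoubleConv(in_ch, in_ch * 2, rng)
        self.up_tr = []
        self.up_conv = []
        ch = in_ch * 2
        for d in reversed(range(config.depth)):
            self.up_tr.append(nn.ConvTranspose2x2(ch, ch // 2, rng))
            self.up_conv.append(_DoubleConv(ch, ch // 2, rng))
            ch //= 2
        self.head = nn.Conv2d(ch, config.n_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Logits of shape (N, n_classes, H, W)."""
        self._check_input(x)
        skips = []
        h = x
        for block in self.down:
            h = block(h)
            skips.append(h)
            h = nn.maxpool2x2(h)
        h = self.bottleneck(h)
        for tr, block, skip in zip(self.up_tr, self.up_conv, reversed(skips)):
            h = tr(h)
            h = nn.concat([skip, h], axis=1)
            h = block(h)
        return self.head(h)

    def _check_input(self, x: Tensor) -> None:
        n, c, h, w = x.shape
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ValueError(
                f"input side {h}x{w} must be divisible by 2^depth = {div} "
                f"so every pooling acts on even feature maps")
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} channels, got {c}")


def build_unet(config: UNetConfig = UNetConfig(),
               seed: int | np.random.Generator = 0) -> UNet:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return UNet(config, rng)


def count_conv_layers(net: UNet) -> int:
    """Convolutional layers, counting transposed and 1x1 convolutions."""
    return nn.count_convs(net)


def encoder_channel_widths(config: UNetConfig) -> list[int]:
    """Channel widths down the contracting path (incl. bottleneck)."""
    return [config.base_width * 2 ** d for d in range(config.depth + 1)]


def _as_batch(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = image[None, None]
    elif image.ndim == 3:
        image = image[:, None]
    return image


def coarse_forward(net: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel 3-class probability map(s) for (H,W), (N,H,W) or (N,C,H,W)."""
    batch = _as_batch(image)
    if not np.all(np.isfinite(batch)):
        raise ValueError("non-finite values in network input")
    logits = net(Tensor(batch))
    probs = nn.softmax_np(logits.data, axis=1)
    return probs[0] if np.asarray(image).ndim == 2 else probs
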