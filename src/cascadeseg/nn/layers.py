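"""Module/parameter containers and the layers used by both network stages."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight container with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(f"{full}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
                    elif isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for val in vars(self).values():
            if isinstance(val, Module):
                out.extend(val.modules())
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_init(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """Stride-1, same-padding 2-D convolution, optionally dilated."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 dilation: int = 1, bias: bool = True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.dilation = kernel, dilation
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution: doubles H and W."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(he_init(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2x2(x, self.weight, self.bias)


class ChannelConv1d(Module):
    """Shared length-K convolution along the channel axis of (N, C) vectors."""

    def __init__(self, k: int, rng):
        if k % 2 == 0:
            raise ValueError("K must be odd")
        self.k = k
        self.weight = Parameter(he_init(rng, (k,), k))

    def forward(self, v: Tensor) -> Tensor:
        return ad.channel_conv1d(v, self.weight)


class ConvRelu(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, dilation: int = 1):
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, dilation=dilation)

    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(self.conv(x))


def count_convs(module: Module) -> int:
    """Number of convolutional layers (incl. transposed and 1x1) in a module."""
    return sum(isinstance(m, (Conv2d, ConvTranspose2x2)) for m in module.modules())
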