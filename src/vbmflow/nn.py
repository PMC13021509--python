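"""Small 3D convolutional network components built on the autodiff engine.

The same UNet backbone serves tissue segmentation (ReLU, multilevel-activation
head) and registration (LeakyReLU, tanh head): depth-``d`` encoder/decoder,
channel doubling per level starting from ``base_channels``, instance
normalization, average-pool downsampling and nearest-neighbor upsampling.
"""
from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor


class Module:
    def parameters(self):
        out = []
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

    def state_dict(self, prefix=""):
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out[prefix + k] = v.data
            elif isinstance(v, Module):
                out.update(v.state_dict(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(f"{prefix}{k}.{i}."))
        return out

    def load_state_dict(self, state, prefix=""):
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                v.data[...] = state[prefix + k]
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{k}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng: np.random.Generator):
        fan_in = in_ch * kernel ** 3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x):
        return ad.conv3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    def __init__(self, ch, eps=1e-5):
        self.gamma = Parameter(np.ones((ch, 1, 1, 1)))
        self.beta = Parameter(np.zeros((ch, 1, 1, 1)))
        self.eps = eps

    def forward(self, x):
        m = ad.tmean(x, axis=(1, 2, 3), keepdims=True)
        xc = x - m
        var = ad.tmean(xc * xc, axis=(1, 2, 3), keepdims=True)
        return self.gamma * (xc / ad.sqrt(var + self.eps)) + self.beta


class ConvBlock(Module):
    """Two conv -> instance-norm -> activation stages."""

    def __init__(self, in_ch, out_ch, rng, activation="relu"):
        self.c1 = Conv3d(in_ch, out_ch, 3, rng)
        self.n1 = InstanceNorm3d(out_ch)
        self.c2 = Conv3d(out_ch, out_ch, 3, rng)
        self.n2 = InstanceNorm3d(out_ch)
        self._act = ad.relu if activation == "relu" else ad.leaky_relu

    def forward(self, x):
        x = self._act(self.n1(self.c1(x)))
        return self._act(self.n2(self.c2(x)))


class UNet3d(Module):
    """Encoder/decoder with channel doubling and skip connections."""

    def __init__(self, in_channels, out_channels, depth=4, base_channels=8,
                 activation="relu", seed=0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        chans = [base_channels * 2 ** i for i in range(depth + 1)]
        self.enc = [ConvBlock(in_channels if i == 0 else chans[i - 1], chans[i], rng, activation)
                    for i in range(depth)]
        self.bottleneck = ConvBlock(chans[depth - 1], chans[depth], rng, activation)
        self.dec = [ConvBlock(chans[i + 1] + chans[i], chans[i], rng, activation)
                    for i in reversed(range(depth))]
        self.head = Conv3d(chans[0], out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for blk in self.enc:
            x = blk(x)
            skips.append(x)
            x = ad.avg_pool3d(x)
        x = self.bottleneck(x)
        for blk, skip in zip(self.dec, reversed(skips)):
            x = ad.upsample_nearest3d(x)
            x = blk(ad.concat([x, skip], axis=0))
        return self.head(x)


def mse_loss(a, b):
    d = ad.as_tensor(a) - ad.as_tensor(b)
    return ad.tmean(d * d)


def mae_loss(a, b):
    return ad.tmean(ad.absolute(ad.as_tensor(a) - ad.as_tensor(b)))
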