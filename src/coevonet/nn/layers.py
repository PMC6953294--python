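"""Neural-network building blocks: modules, conv/linear/batch-norm layers.

Modules hold :class:`~coevonet.nn.autodiff.Tensor` parameters and compose
into the residual trunks used by the contact models.  A "batch" is always a
single protein, so BatchNorm2d normalizes each channel over the two spatial
(residue-pair) axes.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self):
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
        for child in self._children():
            params.extend(child.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for p, arr in zip(params, state):
            p.data = arr.copy()

    def n_parameters(self):
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    """Same-padded 2-D convolution over a (C, L, L) map. He-normal init."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, dtype=np.float32):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return ad.conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features, out_features, rng, dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, std, (in_features, out_features)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Per-channel normalization of a (C, L, L) map over the spatial axes.

    With one protein per batch this is instance normalization in effect;
    running statistics are kept for evaluation mode.
    """

    def __init__(self, channels, dtype=np.float32, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1, 1), dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros((channels, 1, 1), dtype=dtype)
        self.running_var = np.ones((channels, 1, 1), dtype=dtype)

    def __call__(self, x):
        if self.training:
            mu = x.mean(axis=(1, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(1, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * (
                mu.data if isinstance(mu, Tensor) else mu
            )
            self.running_var = (1 - m) * self.running_var + m * (
                var.data if isinstance(var, Tensor) else var
            )
            return xc / ad.sqrt(var + self.eps) * self.gamma + self.beta
        norm = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return norm * self.gamma + self.beta


class ResidualBlock(Module):
    """Pre-activation residual block: two (BN - ReLU - 3x3 conv) layers + skip."""

    def __init__(self, channels, rng, dtype=np.float32, kernel_size=3):
        super().__init__()
        self.bn1 = BatchNorm2d(channels, dtype=dtype)
        self.conv1 = Conv2d(channels, channels, kernel_size, rng, dtype=dtype)
        self.bn2 = BatchNorm2d(channels, dtype=dtype)
        self.conv2 = Conv2d(channels, channels, kernel_size, rng, dtype=dtype)

    def __call__(self, x):
        h = self.conv1(ad.relu(self.bn1(x)))
        h = self.conv2(ad.relu(self.bn2(h)))
        return x + h


class MLP(Module):
    """Small fully connected network applied row-wise, ReLU hidden layers."""

    def __init__(self, widths, rng, dtype=np.float32, final_std=0.1):
        super().__init__()
        self.widths = tuple(widths)
        self.layers = []
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            layer = Linear(a, b, rng, dtype=dtype)
            if i == len(widths) - 2:  # small final layer -> outputs start near 0.5
                layer.weight.data = rng.normal(0.0, final_std, (a, b)).astype(dtype)
                layer.bias.data = np.zeros(b, dtype=dtype)
            self.layers.append(layer)

    def __call__(self, x):
        h = x
        for layer in self.layers[:-1]:
            h = ad.relu(layer(h))
        return self.layers[-1](h)
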