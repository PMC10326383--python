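"""Neural-network building blocks on top of the autodiff engine.

Layout convention is NCHW throughout.  Convolutions are computed as
matrix products against the ``im2col`` patch matrix; transposed
convolutions as the adjoint scatter (``col2im``), which makes both
differentiable to arbitrary order.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: parameter registry plus train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, mod: "Module") -> "Module":
        self._children[name] = mod
        return mod

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {name: t.data for name, t in self._params.items()}
        for cname, child in self._children.items():
            for k, v in child.state_arrays().items():
                out[f"{cname}.{k}"] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        for name, t in self._params.items():
            t.data = np.asarray(state[name], dtype=np.float64).reshape(t.shape)
        for cname, child in self._children.items():
            sub = {k[len(cname) + 1:]: v for k, v in state.items()
                   if k.startswith(cname + ".")}
            child.load_state_arrays(sub)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, *, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = self.register("weight", w)
        self.bias = self.register("bias", np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        ho = ad.conv_out_size(h, self.kernel, self.stride, self.padding)
        wo = ad.conv_out_size(w, self.kernel, self.stride, self.padding)
        cols = ad.im2col(x, self.kernel, self.stride, self.padding)
        out = ad.matmul(self.weight, cols)                  # (N, O, Ho*Wo)
        out = ad.reshape(out, (n, self.out_channels, ho, wo))
        return out + ad.reshape(self.bias, (1, self.out_channels, 1, 1))


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, *, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels * kernel * kernel, in_channels))
        self.weight = self.register("weight", w)
        self.bias = self.register("bias", np.zeros(out_channels))

    def out_size(self, size: int) -> int:
        return (size - 1) * self.stride - 2 * self.padding + self.kernel

    def forward(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        ho, wo = self.out_size(h), self.out_size(w)
        if ho <= 0 or wo <= 0:
            raise ValueError("transposed convolution produced non-positive size")
        xf = ad.reshape(x, (n, self.in_channels, h * w))
        cols = ad.matmul(self.weight, xf)                   # (N, O*k*k, H*W)
        out = ad.col2im(cols, self.out_channels, (ho, wo),
                        self.kernel, self.stride, self.padding)
        return out + ad.reshape(self.bias, (1, self.out_channels, 1, 1))


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.register("gamma", np.ones((1, channels, 1, 1)))
        self.beta = self.register("beta", np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = ad.mean(x, axis=(0, 2, 3), keepdims=True)
            var = ad.mean((x - mu) * (x - mu), axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * ad.pow_(var + Tensor(self.eps), -0.5)
        return self.gamma * xhat + self.beta


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization (no running stats).

    Offered as the critic's normalization switch: batch statistics couple
    the samples of a batch, which interferes with per-sample input
    gradients in the gradient penalty.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = self.register("gamma", np.ones((1, channels, 1, 1)))
        self.beta = self.register("beta", np.zeros((1, channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        mu = ad.mean(x, axis=(2, 3), keepdims=True)
        var = ad.mean((x - mu) * (x - mu), axis=(2, 3), keepdims=True)
        xhat = (x - mu) * ad.pow_(var + Tensor(self.eps), -0.5)
        return self.gamma * xhat + self.beta


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ad.leaky_relu(x, self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.sigmoid(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(self.mods):
            self.add_child(str(i), m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
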