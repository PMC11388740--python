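"""Trainable layer modules on top of the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module", "Parameter", "Sequential", "Conv2d", "Linear", "BatchNorm2d",
    "ReLU", "SELU", "Sigmoid", "UpsampleConvBlock", "ResidualBlock",
    "InceptionBlock",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state export."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # state includes non-trainable buffers (batch-norm running stats)
    def state_dict(self, prefix: str = ""):
        state = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                state[prefix + name] = val.data.copy()
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                state[prefix + name] = val.copy()
        for cname, child in self._children():
            state.update(child.state_dict(prefix + cname + "."))
        return state

    def load_state_dict(self, state):
        for name, val in vars(self).items():
            key = name
            if isinstance(val, Parameter):
                val.data[...] = state[key] if key in state else val.data
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                if key in state:
                    val[...] = state[key]
        # children need prefixed access; re-walk with full keys
        for cname, child in self._children():
            sub = {k[len(cname) + 1:]: v for k, v in state.items()
                   if k.startswith(cname + ".")}
            child.load_state_dict(sub)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel // 2  # shape-preserving at stride 1
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones((1, num_ch, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_ch, 1, 1)))
        self.running_mean = np.zeros((1, num_ch, 1, 1))
        self.running_var = np.ones((1, num_ch, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xn = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xn = (x - Tensor(self.running_mean)) * \
                Tensor(1.0 / np.sqrt(self.running_var + self.eps))
        return xn * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SELU(Module):
    def forward(self, x):
        return x.selu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class UpsampleConvBlock(Module):
    """Decoder block: nearest 2x upsample + 3x3 conv + BN + ReLU.

    Plays the role of a strided transposed-convolution block in a
    simple-baselines style decoder while avoiding checkerboard artifacts.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return self.bn(self.conv(x.upsample_nearest(2))).relu()


class ResidualBlock(Module):
    """Two 3x3 convs with BN + SELU and an identity skip."""

    def __init__(self, ch: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = Conv2d(ch, ch, 3, rng=rng)
        self.b1 = BatchNorm2d(ch)
        self.c2 = Conv2d(ch, ch, 3, rng=rng)
        self.b2 = BatchNorm2d(ch)

    def forward(self, x):
        y = self.b1(self.c1(x)).selu()
        y = self.b2(self.c2(y)).selu()
        return x + y


class InceptionBlock(Module):
    """Classic inception: parallel 1x1 / 3x3 / 5x5 / pooled 1x1 branches."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        b = max(out_ch // 4, 1)
        last = out_ch - 3 * b
        self.c1 = Conv2d(in_ch, b, 1, rng=rng)
        self.c3 = Conv2d(in_ch, b, 3, rng=rng)
        self.c5 = Conv2d(in_ch, b, 5, rng=rng)
        self.cp = Conv2d(in_ch, last, 1, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        pooled = x.max_pool2d(3, stride=1, padding=1)
        y = concat([self.c1(x), self.c3(x), self.c5(x), self.cp(pooled)], axis=1)
        return self.bn(y).selu()
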