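"""Layer/module abstractions over the autograd core."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ConvBlock",
    "Sequential",
]


class Module:
    """Base class: parameter discovery by attribute recursion, train/eval."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            params.extend(_collect(v))
        return params

    def named_parameters(self, prefix=""):
        out = []
        for k, v in self.__dict__.items():
            out.extend(_collect_named(v, f"{prefix}{k}"))
        return out

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            mods.extend(_collect_modules(v))
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                d[f"__bn{i}_mean"] = m.running_mean.copy()
                d[f"__bn{i}_var"] = m.running_var.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(d[name], dtype=np.float32).copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                if f"__bn{i}_mean" in d:
                    m.running_mean = np.asarray(d[f"__bn{i}_mean"], dtype=np.float32).copy()
                    m.running_var = np.asarray(d[f"__bn{i}_var"], dtype=np.float32).copy()
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v):
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_named(v, name):
    if isinstance(v, Tensor) and v.requires_grad:
        return [(name, v)]
    if isinstance(v, Module):
        return [(f"{name}.{n}", p) for n, p in v.named_parameters()]
    if isinstance(v, (list, tuple)):
        out = []
        for i, item in enumerate(v):
            out.extend(_collect_named(item, f"{name}.{i}"))
        return out
    return []


def _collect_modules(v):
    if isinstance(v, Module):
        return v.modules()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect_modules(item))
        return out
    return []


class Conv2d(Module):
    """Same-padded stride-1 convolution with He-initialised weights."""

    def __init__(self, in_ch, out_ch, k=3, dilation=1, rng=None, bias=True):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_ch, in_ch, k, k)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.dilation = dilation

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    """Per-channel normalisation with batch statistics and running averages."""

    def __init__(self, n_ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        if self.training:
            out, mu, var = ag.batchnorm2d(x, self.gamma, self.beta, self.eps)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
            return out
        mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ag.mul(ag.add(x, Tensor(-mu[None, :, None, None])),
                      Tensor(inv[None, :, None, None]))
        g = ag.reshape(self.gamma, (1, -1, 1, 1))
        b = ag.reshape(self.beta, (1, -1, 1, 1))
        return ag.add(ag.mul(xhat, g), b)


class Linear(Module):
    def __init__(self, in_f, out_f, rng=None, bias=True):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, std, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True) if bias else None

    def forward(self, x):
        out = ag.matmul(x, self.weight)
        if self.bias is not None:
            out = ag.add(out, self.bias)
        return out


class ConvBlock(Module):
    """Conv-BN-ReLU twice: the standard U-Net block."""

    def __init__(self, in_ch, out_ch, rng=None):
        super().__init__()
        self.c1 = Conv2d(in_ch, out_ch, rng=rng)
        self.n1 = BatchNorm2d(out_ch)
        self.c2 = Conv2d(out_ch, out_ch, rng=rng)
        self.n2 = BatchNorm2d(out_ch)

    def forward(self, x):
        x = ag.relu(self.n1(self.c1(x)))
        return ag.relu(self.n2(self.c2(x)))


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
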