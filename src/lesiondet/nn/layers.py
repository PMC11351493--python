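"""Layer modules and a momentum-SGD optimizer on top of the tape engine."""

from __future__ import annotations

import math

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "SGD", "Adam"]


class Module:
    """Parameter container with recursive traversal and a train/eval flag.

    Sub-modules and parameters are discovered by walking instance attributes
    (lists of modules are walked too), so layers register themselves simply
    by assignment, mirroring the familiar torch idiom.
    """

    def __init__(self):
        self.training = True

    def children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for c in self.children():
            yield from c.modules()

    def parameters(self):
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    yield v

    def named_parameters(self, prefix=""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        # running statistics live outside the parameter list
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bnstat{i}.mean"] = m.running_mean.copy()
                state[f"__bnstat{i}.var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean[...] = state[f"__bnstat{i}.mean"]
                m.running_var[...] = state[f"__bnstat{i}.var"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k, *, stride: int = 1,
                 dilation: int = 1, groups: int = 1, bias: bool = True,
                 padding="same", rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(k, int):
            k = (k, k)
        rng = rng or np.random.default_rng(0)
        fan_in = (c_in // groups) * k[0] * k[1]
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, (c_out, c_in // groups, *k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride, self.dilation, self.groups = stride, dilation, groups
        if padding == "same":
            if stride == 1:
                self.padding = None  # resolved per-axis inside conv2d
            else:
                # standard 'same-ish' padding for stride-2 downsampling
                self.padding = ((k[0] - 1) * dilation // 2, (k[1] - 1) * dilation // 2)
        else:
            self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation,
                        groups=self.groups)


class BatchNorm2d(Module):
    """Per-channel normalization over (N, H, W).

    With a single-sample batch the batch statistics are degenerate, so the
    layer falls back to per-instance statistics over (H, W) in training mode.
    Evaluation always uses the running averages.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            axes = (0, 2, 3) if x.shape[0] > 1 else (2, 3)
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            if x.shape[0] > 1:
                m = self.momentum
                self.running_mean += m * (mu.data.reshape(-1) - self.running_mean)
                self.running_var += m * (var.data.reshape(-1) - self.running_var)
            xn = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xn * g + b


class SGD:
    """SGD with classical momentum and optional decoupled weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, max_grad_norm: float | None = 10.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.max_grad_norm = max_grad_norm
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def _clip(self):
        total = math.sqrt(sum(float((p.grad ** 2).sum())
                              for p in self.params if p.grad is not None))
        if total > self.max_grad_norm:
            scale = self.max_grad_norm / (total + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self):
        if self.max_grad_norm is not None:
            self._clip()
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class Adam:
    """Adam with optional gradient-norm clipping."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 max_grad_norm: float | None = 10.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.max_grad_norm = max_grad_norm
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    zero_grad = SGD.zero_grad
    _clip = SGD._clip

    def step(self):
        if self.max_grad_norm is not None:
            self._clip()
        self._t += 1
        bc1 = 1.0 - self.b1 ** self._t
        bc2 = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
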