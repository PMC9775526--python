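"""Layers and optimization on top of :mod:`sleepgan.autodiff`.

Covers exactly what the epoch generator/discriminator and the relational
memory cell need: 1D conv blocks with batch normalization, linear maps,
embeddings, layer norm, and Adam with per-group learning rates plus a
step-decay schedule.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class with parameter traversal and a train/eval flag."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """All parameter arrays (views), for checkpointing/comparison."""
        return [p.data for p in self.parameters()]


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype=np.float64):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1d(Module):
    """Same-padded stride-1 1D convolution (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, (c_out, c_in, kernel), c_in * kernel), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias)

    def set_identity(self):
        """Center-tap identity kernel (requires c_in == c_out); used in tests
        to trace residual paths with known weights."""
        w = np.zeros_like(self.weight.data)
        c_out, c_in, k = w.shape
        if c_in != c_out:
            raise ValueError("identity kernel needs matching channels")
        w[np.arange(c_out), np.arange(c_in), k // 2] = 1.0
        self.weight.data = w
        self.bias.data = np.zeros_like(self.bias.data)


class BatchNorm1d(Module):
    """Batch normalization over (batch, length) per channel.

    Training mode normalizes with batch statistics and updates running
    averages; eval mode uses the running averages (so a frozen stage is
    fully static).
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = ad.mean(x, axis=(0, 2), keepdims=True)
            xc = x - mu
            var = ad.mean(xc * xc, axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
            inv = ad.power(var + self.eps, -0.5)
            y = xc * inv
        else:
            mu = self.running_mean[None, :, None]
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            y = (x - Tensor(mu)) * Tensor(inv[None, :, None])
        return y * self.gamma.reshape((1, -1, 1)) + self.beta.reshape((1, -1, 1))

    def set_identity(self):
        self.gamma.data = np.ones_like(self.gamma.data)
        self.beta.data = np.zeros_like(self.beta.data)
        self.running_mean = np.zeros_like(self.running_mean)
        self.running_var = np.ones_like(self.running_var)
        self.eps = 0.0  # exact pass-through for residual-path tracing
        self.eval()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, (d_in, d_out), d_in), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.standard_normal((n_tokens, dim)) * 0.1, requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ad.take(self.weight, np.asarray(idx))


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then affine."""
    mu = ad.mean(x, axis=-1, keepdims=True)
    xc = x - mu
    var = ad.mean(xc * xc, axis=-1, keepdims=True)
    return xc * ad.power(var + eps, -0.5) * gamma + beta


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))  # detached shift
    z = x - m
    return z - ad.log(ad.sum_(ad.exp(z), axis=axis, keepdims=True))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return ad.exp(log_softmax(x, axis=axis))


class Adam:
    """Adam over parameter groups, each with its own learning rate.

    ``groups`` is a list of dicts: ``{"params": [...], "lr": float}``.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps: float = 1e-8):
        self.groups = [{"params": list(g["params"]), "lr": float(g["lr"])} for g in groups]
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self):
        self.t += 1
        for g in self.groups:
            for p in g["params"]:
                if p.grad is None:
                    continue
                grad = p.grad
                m = self._m.setdefault(id(p), np.zeros_like(p.data))
                v = self._v.setdefault(id(p), np.zeros_like(p.data))
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad * grad
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p.data = p.data - g["lr"] * mhat / (np.sqrt(vhat) + self.eps)

    def scale_lr(self, factor: float):
        for g in self.groups:
            g["lr"] *= factor
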