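"""Neural-network layers and optimizers on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor, concat, conv2d, log_softmax, maxpool2d, softmax

__all__ = [
    "Module", "Linear", "Conv2d", "BatchNorm2d", "BatchNorm1d", "LayerNorm",
    "MultiHeadSelfAttention", "Adam", "SGDM",
    "Tensor", "concat", "conv2d", "maxpool2d", "softmax", "log_softmax",
]


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


def xavier_init(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    """Tiny module base: recursively collects parameters from attributes."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_vector(self) -> np.ndarray:
        return np.concatenate([p.data.ravel() for p in self.parameters()])

    def load_state_vector(self, vec: np.ndarray):
        i = 0
        for p in self.parameters():
            n = p.data.size
            p.data = vec[i : i + n].reshape(p.data.shape).astype(DTYPE)
            i += n

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init: str = "xavier"):
        if init == "he":
            w = he_init(rng, (d_in, d_out), d_in)
        else:
            w = xavier_init(rng, (d_in, d_out), d_in, d_out)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, groups: int = 1, init: str = "he"):
        fan_in = (c_in // groups) * k * k
        shape = (c_out, c_in // groups, k, k)
        w = he_init(rng, shape, fan_in) if init == "he" else xavier_init(
            rng, shape, fan_in, c_out * k * k
        )
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)
        self.stride, self.pad, self.groups = stride, pad, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.pad, self.groups)


class _BatchNorm(Module):
    """Normalize with batch statistics in training, running stats in eval."""

    def __init__(self, c: int, axes: tuple, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.axes, self.momentum, self.eps = axes, momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import batchnorm

        if self.training:
            mu = x.data.mean(axis=self.axes)
            var = x.data.var(axis=self.axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        return batchnorm(x, self.gamma, self.beta, mu, var, self.axes,
                         self.eps, use_batch_stats=self.training)


class BatchNorm2d(_BatchNorm):
    def __init__(self, c: int, **kw):
        super().__init__(c, axes=(0, 2, 3), **kw)


class BatchNorm1d(_BatchNorm):
    def __init__(self, c: int, **kw):
        super().__init__(c, axes=(0,), **kw)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product multi-head self-attention over tokens.

    Input/output shape (B, T, D).  Set `force_uniform=True` to replace the
    attention weights with a uniform distribution (plain token averaging),
    used by equivalence tests.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError(f"token dim {d} not divisible by {n_heads} heads")
        self.d, self.n_heads, self.dh = d, n_heads, d // n_heads
        self.qkv = Linear(d, 3 * d, rng, init="xavier")
        self.proj = Linear(d, d, rng, init="xavier")
        self.force_uniform = False

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        qkv = self.qkv(x).reshape(B, T, 3, self.n_heads, self.dh)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, h, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        if self.force_uniform:
            att = Tensor(np.full((B, self.n_heads, T, T), 1.0 / T, dtype=DTYPE))
        else:
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
            att = softmax(scores, axis=-1)
        out = att @ v  # (B, h, T, dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.proj(out)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGDM:
    """SGD with classical momentum ('sgdm')."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, momentum: float = 0.9):
        self.params, self.lr, self.momentum = params, lr, momentum
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.v[i] = self.momentum * self.v[i] - self.lr * p.grad
            p.data = p.data + self.v[i]
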