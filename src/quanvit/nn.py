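"""Neural-network layers and the Adam optimizer, built on `quanvit.autograd`.

NHWC layout for images, (batch, tokens, dim) for sequences.  Weight
initialization is seeded truncated-normal; normalization layers start at
identity, with the final per-block norm scale zero-initialized so each
residual block starts as the identity map.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, gelu, log_softmax

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "MaxPool2d",
    "BatchChannelNorm",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "Adam",
    "cross_entropy",
    "same_padding",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated-normal draw at +-2 std (resampling tails)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal parameter container with train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        seen = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    yield p

    def train(self, mode: bool = True):
        self.training = mode
        for value in self.__dict__.values():
            for m in _collect_modules(value):
                m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for m in _collect_modules(self):
            if hasattr(m, "running_mean"):  # normalization buffers
                state.append(m.running_mean.copy())
                state.append(m.running_var.copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = list(self.parameters())
        norms = [m for m in _collect_modules(self) if hasattr(m, "running_mean")]
        if len(params) + 2 * len(norms) != len(state):
            raise ValueError("state does not match parameter/buffer list")
        for p, d in zip(params, state):
            p.data = d.copy()
        rest = state[len(params):]
        for m, mean, var in zip(norms, rest[0::2], rest[1::2]):
            m.running_mean = mean.copy()
            m.running_var = var.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_modules(value):
    if isinstance(value, Module):
        yield value
        for v in value.__dict__.values():
            yield from _collect_modules(v)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)


def same_padding(size: int, kernel: int, stride: int) -> tuple[int, int]:
    """(before, after) zero padding giving ceil(size/stride) outputs."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, std: float = 0.02):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (in_dim, out_dim), std))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class Conv2d(Module):
    """k x k convolution, NHWC, 'valid' or 'same' symmetric zero padding."""

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1, padding: str = "same", bias: bool = True):
        super().__init__()
        std = (2.0 / (kernel * kernel * c_in)) ** 0.5  # He-style fan-in
        self.weight = Parameter(rng.normal(0.0, std, (kernel, kernel, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out

    def _pads(self, shape) -> tuple[int, int, int, int]:
        if self.padding == "valid":
            return (0, 0, 0, 0)
        t, b = same_padding(shape[1], self.kernel, self.stride)
        l, r = same_padding(shape[2], self.kernel, self.stride)
        return (t, b, l, r)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self._pads(x.shape))


class MaxPool2d(Module):
    def __init__(self, window: int, stride: int, padding: str = "same"):
        super().__init__()
        self.window, self.stride, self.padding = window, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        if self.padding == "valid":
            pads = (0, 0, 0, 0)
        else:
            t, b = same_padding(x.shape[1], self.window, self.stride)
            l, r = same_padding(x.shape[2], self.window, self.stride)
            pads = (t, b, l, r)
        return x.maxpool2d((self.window, self.window), self.stride, pads)


class BatchChannelNorm(Module):
    """Per-channel normalization with trainable affine, NHWC.

    Batch statistics during training, running averages at evaluation —
    the standard arrangement that keeps deep residual stacks trainable.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 zero_init: bool = False):
        super().__init__()
        self.gamma = Parameter(np.zeros(channels) if zero_init else np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self._stat_batches: list | None = None

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 1, 2), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 1, 2), keepdims=True)
            if self._stat_batches is not None:
                self._stat_batches.append((mean.data.ravel(), var.data.ravel()))
            else:
                self.running_mean += self.momentum * (
                    mean.data.ravel() - self.running_mean
                )
                self.running_var += self.momentum * (
                    var.data.ravel() - self.running_var
                )
            xn = centered * (var + self.eps) ** -0.5
        else:
            xn = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xn * self.gamma + self.beta

    def begin_stat_refresh(self) -> None:
        self._stat_batches = []

    def end_stat_refresh(self) -> None:
        """Replace running statistics by the average over collected batches.

        Used for a precise re-estimation pass after each training epoch, so
        evaluation statistics match the current weights instead of lagging
        them by the EMA horizon.
        """
        if self._stat_batches:
            means = np.stack([m for m, _ in self._stat_batches])
            varis = np.stack([v for _, v in self._stat_batches])
            self.running_mean = means.mean(axis=0)
            self.running_var = varis.mean(axis=0)
        self._stat_batches = None


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centered = x - mean
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import softmax

        n, t, d = x.shape
        h, dh = self.heads, self.head_dim
        qkv = self.qkv(x)  # (n, t, 3d)
        q = qkv[:, :, :d].reshape(n, t, h, dh).transpose((0, 2, 1, 3))
        k = qkv[:, :, d : 2 * d].reshape(n, t, h, dh).transpose((0, 2, 1, 3))
        v = qkv[:, :, 2 * d :].reshape(n, t, h, dh).transpose((0, 2, 1, 3))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (dh**-0.5)
        att = softmax(scores, axis=-1)
        out = (att @ v).transpose((0, 2, 1, 3)).reshape(n, t, d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-LayerNorm transformer encoder block (attention + GELU MLP)."""

    def __init__(self, dim: int, heads: int, mlp_dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_dim, rng)
        self.fc2 = Linear(mlp_dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(gelu(self.fc1(self.norm2(x))))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood for integer class labels."""
    logp = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), labels]
    return -picked.mean()


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
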