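"""Neural-network building blocks on top of :mod:`lofdti.autograd`.

Conventions: sequence tensors are ``(batch, length, channels)``; masks are
``(batch, length, 1)`` float arrays with 1.0 at real positions.  Batch
normalization is mask-aware so that padding positions never influence the
statistics (this is what makes the encoders padding-invariant).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "Embedding",
    "MaskedBatchNorm",
    "Dropout",
    "conv1d_same",
    "Conv1d",
    "maxpool1d",
    "Adam",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for module in self.modules():
            for value in module.__dict__.values():
                if isinstance(value, Parameter):
                    params.append(value)
                elif isinstance(value, (list, tuple)):
                    params.extend(v for v in value if isinstance(v, Parameter))
        return params

    def train(self) -> "Module":
        for module in self.modules():
            module.training = True
        return self

    def eval(self) -> "Module":
        for module in self.modules():
            module.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- checkpointing --------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                state[key] = value.data.copy()
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                state[key] = value.copy()
            elif isinstance(value, Module):
                state.update(value.state_dict(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        state[f"{key}.{i}"] = item.data.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                value.data = np.array(state[key], dtype=np.float64)
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                setattr(self, name, np.array(state[key], dtype=np.float64))
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        item.data = np.array(state[f"{key}.{i}"], dtype=np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLP(Module):
    """Fully connected stack with ReLU between layers (not after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 1.0 / np.sqrt(dim), size=(n_tokens, dim)))

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.weight.take_rows(indices)


class MaskedBatchNorm(Module):
    """Batch norm over the channel axis using only unmasked positions.

    Statistics are taken over all leading axes; padded rows are excluded
    so adding dummy nodes never changes real-node outputs.
    """

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if mask is None:
            mask = np.ones(x.shape[:-1] + (1,))
        count = float(mask.sum())
        if self.training:
            mean = (x * mask).sum(axis=axes) * (1.0 / count)
            centered = (x - mean) * mask
            var = (centered * centered).sum(axis=axes) * (1.0 / count)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean.data
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data
        else:
            mean = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mean) * (var + self.eps) ** -0.5
        return (xhat * self.gamma + self.beta) * mask


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * keep


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """1-D convolution along axis 1 with zero same-padding.

    x: (B, L, C_in); weight: (K, C_in, C_out) -> (B, L, C_out).
    Implemented as a custom graph node via sliding windows.
    """
    k, c_in, c_out = weight.shape
    B, L, _ = x.shape
    pad_left, pad_right = (k - 1) // 2, k // 2
    xp = np.pad(x.data, ((0, 0), (pad_left, pad_right), (0, 0)))
    # windows flattened to (B*L, K*C_in) so the contraction is one BLAS call
    windows = np.ascontiguousarray(
        np.lib.stride_tricks.sliding_window_view(xp, k, axis=1).transpose(0, 1, 3, 2)
    ).reshape(B * L, k * c_in)
    w2 = weight.data.reshape(k * c_in, c_out)
    data = (windows @ w2).reshape(B, L, c_out)
    if bias is not None:
        data = data + bias.data

    out = Tensor(data)
    inputs = [t for t in (x, weight, bias) if t is not None and t.requires_grad]
    out.requires_grad = bool(inputs)
    out._prev = tuple(inputs)

    def backward(g):
        g2 = g.reshape(B * L, c_out)
        if weight.requires_grad:
            weight._accumulate((windows.T @ g2).reshape(k, c_in, c_out))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            gwin = (g2 @ w2.T).reshape(B, L, k, c_in)
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, j : j + L, :] += gwin[:, :, j, :]
            x._accumulate(gxp[:, pad_left : pad_left + L, :])

    out._backward = backward
    return out


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = Parameter(
            _glorot(rng, fan_in, out_channels, (kernel_size, in_channels, out_channels))
        )
        self.bias = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.weight, self.bias)


def maxpool1d(x: Tensor, window: int, pad_value: float = -1e30) -> Tensor:
    """Non-overlapping max pooling along axis 1 (stride = window)."""
    B, L, C = x.shape
    remainder = (-L) % window
    if remainder:
        pad = Tensor(np.full((B, remainder, C), pad_value))
        x = concat([x, pad], axis=1)
    return x.reshape(B, (L + remainder) // window, window, C).max(axis=2)


class Adam:
    """Adam optimizer (Kingma & Ba) over a parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = np.asarray(p.grad, dtype=np.float64)
            m, v = self.m[i], self.v[i]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
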