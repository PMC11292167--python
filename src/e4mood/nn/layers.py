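"""Neural-network building blocks on top of the autodiff tensors.

Modules hold named parameters, support train/eval switching, and expose
``state_dict``/``load_state_dict`` for flat named-array checkpoints.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv1d_same, maxpool1d, softmax

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "LayerNorm",
    "Dropout",
    "MultiheadSelfAttention",
    "TransformerEncoderLayer",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter/child discovery by attribute inspection."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def _children(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self, flag: bool = True):
        self.training = flag
        for child in self._children():
            child.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing ------------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, np.ndarray):
                yield full, value
            elif isinstance(value, Module):
                yield from value._named_buffers(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{full}.{i}")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{n}": b.copy() for n, b in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, array in state.items():
            if name.startswith("buffer:"):
                buffers[name[len("buffer:"):]][...] = array
            else:
                params[name].data[...] = array

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_xavier(rng, in_features, out_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Same-padding, stride-1 1D convolution: (B, C_in, L) -> (B, C_out, L)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = Parameter(
            _xavier(rng, fan_in, out_channels * kernel_size,
                    (out_channels, in_channels, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels))
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.weight, self.bias)


class BatchNorm1d(Module):
    """BatchNorm over (B, C, L): per-channel statistics over batch and length."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=(0, 2), keepdims=True)
            self.running_mean += self.momentum * (mean.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
            xhat = (x - mean) * (var + self.eps) ** -0.5
        else:
            mean = self.running_mean[None, :, None]
            var = self.running_var[None, :, None]
            xhat = (x + Tensor(-mean)) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mean) * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(float) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiheadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)  # (B, N, 3D)
        qkv = qkv.reshape(B, N, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3, B, h, N, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))  # (B, h, N, N)
        attn = softmax(scores, axis=-1)
        ctx = attn @ v  # (B, h, N, dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm transformer block: LN(x + MHSA(x)), then LN(x + FFN(x))."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.norm2 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x)))
        x = self.norm2(x + self.drop(self.ff2(self.drop(self.ff1(x).gelu()))))
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
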