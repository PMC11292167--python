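"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Only the operations the models in this package need are implemented: basic
broadcasting arithmetic, matmul (batched), reshape/transpose/slice/concat,
reductions, a handful of nonlinearities, softmax cross-entropy, 1D
convolution with same padding, and non-overlapping 1D max pooling.  Every
operation's gradient is verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concatenate", "softmax", "cross_entropy", "conv1d_same", "maxpool1d"]


class Tensor:
    """An ndarray plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_tensor(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = self._as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, _parents=(self,), _backward=backward)

    def __sub__(self, other):
        return self + (-self._as_tensor(other))

    def __rsub__(self, other):
        return self._as_tensor(other) + (-self)

    def __mul__(self, other):
        other = self._as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def __matmul__(self, other):
        other = self._as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], (tuple, list)) else shape
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def transpose(self, *axes):
        axes = axes[0] if len(axes) == 1 and isinstance(axes[0], (tuple, list)) else axes
        inv = np.argsort(axes)
        out_data = np.transpose(self.data, axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g2, self.data.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = math.prod(self.data.shape[a] for a in axes)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def gelu(self):
        """Exact Gaussian error linear unit: x * Phi(x)."""
        x = self.data
        phi = 0.5 * (1.0 + _erf(x / np.sqrt(2.0)))
        out_data = x * phi

        def backward(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
                self._accum(g * (phi + x * pdf))

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def sqrt(self):
        return self ** 0.5


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, dim in enumerate(shape):
        if dim == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + Tensor(-x.data.max(axis=axis, keepdims=True))  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``targets`` under softmax logits.

    ``logits`` may have shape (B, K) or (B, C, K) with targets of matching
    leading shape; the mean is over all leading positions.
    """
    targets = np.asarray(targets)
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    logsum = np.log(np.exp(z - zmax).sum(axis=-1, keepdims=True)) + zmax
    probs = np.exp(z - logsum)
    idx = tuple(np.indices(targets.shape)) + (targets,)
    nll = (logsum.squeeze(-1) - z[idx]).mean()
    n = targets.size

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[idx] -= 1.0
            logits._accum(g * grad / n)

    return Tensor(nll, _parents=(logits,), _backward=backward)


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """1D convolution with same padding and stride 1.

    ``x``: (B, C_in, L); ``weight``: (C_out, C_in, K); ``bias``: (C_out,).
    Output: (B, C_out, L).  Implemented as cross-correlation (the usual deep
    learning convention).
    """
    B, C_in, L = x.data.shape
    C_out, _, K = weight.data.shape
    pad_left = (K - 1) // 2
    pad_right = K - 1 - pad_left
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_left, pad_right)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B, C_in, L, K)
    out_data = np.einsum("bclk,ock->bol", windows, weight.data, optimize=True)
    out_data += bias.data[None, :, None]

    def backward(g):
        if weight.requires_grad:
            gw = np.einsum("bol,bclk->ock", g, windows, optimize=True)
            weight._accum(gw)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            # full correlation of g with flipped kernels
            gp = np.pad(g, ((0, 0), (0, 0), (pad_right, pad_left)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, K, axis=2)  # (B, C_out, L, K)
            w_flip = weight.data[:, :, ::-1]
            gx = np.einsum("bolk,ock->bcl", gwin, w_flip, optimize=True)
            x._accum(gx)

    return Tensor(out_data, _parents=(x, weight, bias), _backward=backward)


def maxpool1d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping max pooling with kernel == stride; L must divide."""
    B, C, L = x.data.shape
    if L % kernel != 0:
        raise ValueError(f"length {L} not divisible by pooling kernel {kernel}")
    xr = x.data.reshape(B, C, L // kernel, kernel)
    arg = xr.argmax(axis=3)
    out_data = np.take_along_axis(xr, arg[..., None], axis=3).squeeze(3)

    def backward(g):
        if x.requires_grad:
            gr = np.zeros_like(xr)
            np.put_along_axis(gr, arg[..., None], g[..., None], axis=3)
            x._accum(gr.reshape(B, C, L))

    return Tensor(out_data, _parents=(x,), _backward=backward)
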