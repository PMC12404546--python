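"""Minimal CNN building blocks on numpy with hand-written backprop.

Everything uses channels-last (NHWC) layout: with the channel axis
innermost, the im2col patch matrix is built from contiguous slice copies
and both the convolution forward and backward reduce to single BLAS
matmuls, which keeps a pure-numpy training loop fast on one CPU.

Layers cache what their backward pass needs during
``forward(..., train=True)``; ``backward`` consumes those caches,
accumulates parameter gradients in place and returns the gradient with
respect to the layer input.  The engine is intentionally small: just the
pieces the prior-guided classifier needs (conv, batch norm, pooling, layer
norm, linear, ReLU), a cross-entropy loss and momentum SGD.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: compute dtype for parameters and activations; float32 keeps the conv
#: matmuls at BLAS speed.  Tests that need tighter numerics (gradient
#: checks) may set this to float64 before building their layers.
DTYPE = np.float32

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Flatten",
    "Linear",
    "LayerNorm",
    "softmax",
    "cross_entropy",
    "SGD",
    "count_parameters",
]


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: a forward/backward pair plus parameter bookkeeping."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- checkpointing ------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays (parameters + buffers) in a fixed order."""
        arrays = [p.data for p in self.parameters()]
        arrays.extend(self._buffers())
        return arrays

    def _buffers(self) -> list[np.ndarray]:
        buffers: list[np.ndarray] = []
        for value in vars(self).values():
            if isinstance(value, Module):
                buffers.extend(value._buffers())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        buffers.extend(item._buffers())
        return buffers

    def state_dict(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError(
                f"state length {len(state)} does not match module ({len(arrays)})"
            )
        for dst, src in zip(arrays, state):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Conv2d(Module):
    """2-D convolution via channels-last im2col.

    Input ``(N, H, W, C_in)``; weights are stored ``(k, k, C_in, C_out)``
    so the flattened patch matrix multiplies them directly.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.stride = stride
        self.padding = (k - 1) // 2 if padding is None else padding
        fan_in = in_channels * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(k, k, in_channels, out_channels)),
            "conv.weight",
        )
        self.bias = Parameter(np.zeros(out_channels), "conv.bias") if bias else None

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, _, _, c = xp.shape
        k, s = self.kernel_size, self.stride
        cols = np.empty((n, ho, wo, k, k, c), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = xp[:, i : i + ho * s : s, j : j + wo * s : s, :]
        return cols.reshape(n * ho * wo, k * k * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = self._im2col(xp, ho, wo)
        w_mat = self.weight.data.reshape(-1, self.out_channels)
        out = cols @ w_mat
        if self.bias is not None:
            out += self.bias.data
        if train:
            self._cols = cols
            self._x_shape = (n, h, w, c)
            self._out_hw = (ho, wo)
        return out.reshape(n, ho, wo, self.out_channels)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        ho, wo = self._out_hw
        gflat = grad.reshape(n * ho * wo, self.out_channels)
        w_mat = self.weight.data.reshape(-1, self.out_channels)
        self.weight.grad += (self._cols.T @ gflat).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += gflat.sum(axis=0)
        dcols = (gflat @ w_mat.T).reshape(n, ho, wo, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + ho * s : s, j : j + wo * s : s, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, channels-last."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def _buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean[...] = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var[...] = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._xhat = xhat
            self._inv_std = inv_std
            self._m = x.shape[0] * x.shape[1] * x.shape[2]
        return self.gamma.data * xhat + self.beta.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        g = grad * self.gamma.data
        sum_g = g.sum(axis=(0, 1, 2))
        sum_gx = (g * xhat).sum(axis=(0, 1, 2))
        dx = inv_std / m * (m * g - sum_g - xhat * sum_gx)
        self._xhat = None
        return dx


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0) -> None:
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(
                x, ((0, 0), (p, p), (p, p), (0, 0)), constant_values=-np.inf
            )
        windows = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        flat = windows.reshape(*windows.shape[:4], k * k)  # (n, ho, wo, c, k*k)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._x_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        n, hp, wp, c = self._x_shape
        dxp = np.zeros((n, hp, wp, c), dtype=grad.dtype)
        rows, cols = np.divmod(self._argmax, k)
        n_idx, i_idx, j_idx, c_idx = np.indices(grad.shape)
        np.add.at(dxp, (n_idx, i_idx * s + rows, j_idx * s + cols, c_idx), grad)
        h, w = hp - 2 * p, wp - 2 * p
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class GlobalAvgPool2d(Module):
    """Adaptive average pooling to 1x1, returned as (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._spatial = x.shape[1:3]
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, w = self._spatial
        n, c = grad.shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), (n, h, w, c)).copy()


class Flatten(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(out_features, in_features)), "linear.weight"
        )
        self.bias = Parameter(np.zeros(out_features), "linear.bias") if bias else None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        dx = grad @ self.weight.data
        self._x = None
        return dx


class LayerNorm(Module):
    """Normalization over the last axis of an (N, D) input."""

    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        self.dim = dim
        self.eps = eps
        self.gamma = Parameter(np.ones(dim), "ln.gamma")
        self.beta = Parameter(np.zeros(dim), "ln.beta")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._xhat, self._inv_std = xhat, inv_std
        return self.gamma.data * xhat + self.beta.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        d = self.dim
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.data
        dx = inv_std / d * (
            d * g
            - g.sum(axis=-1, keepdims=True)
            - xhat * (g * xhat).sum(axis=-1, keepdims=True)
        )
        self._xhat = None
        return dx


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and the gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(probs[np.arange(n), targets] + 1e-300))
    grad = probs
    grad[np.arange(n), targets] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def count_parameters(module: Module) -> int:
    """Exact number of trainable scalars in a module."""
    return int(sum(p.size for p in module.parameters()))
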