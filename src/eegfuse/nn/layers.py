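"""Layer primitives with explicit forward/backward passes.

Tensors are NCHW float32 (or NF for dense layers).  Convolutions are 3x3,
stride 1, "same" padding; pooling is 2x2 non-overlapping max.  The backward
pass of the convolution reuses the im2col forward machinery: the input
gradient of a stride-1 same conv equals a same conv of the output gradient
with the spatially flipped, channel-transposed kernel.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; stateless layers override ``forward``/``backward`` only."""

    #: ordered parameter names ('' if none)
    param_names: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.param_names}

    def grads(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, "d_" + name) for name in self.param_names}


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for stride-1 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = sliding_window_view(xp, (k, k), axis=(2, 3))  # N, C, H, W, k, k
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


class Conv2D(Layer):
    """3x3 stride-1 same convolution with bias; He-normal initialization."""

    param_names = ("weight", "bias")

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel_size: int = 3):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = rng.standard_normal(
            (out_channels, in_channels, kernel_size, kernel_size), dtype=np.float32
        ) * np.float32(np.sqrt(2.0 / fan_in))
        self.bias = np.zeros(out_channels, dtype=np.float32)
        self.d_weight = np.zeros_like(self.weight)
        self.d_bias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel_size
        cols = _im2col(x, k, k // 2)
        out = cols @ self.weight.reshape(self.out_channels, -1).T + self.bias
        if train:
            self._cols, self._in_shape = cols, x.shape
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, _, h, w = grad_out.shape
        k = self.kernel_size
        g = grad_out.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        self.d_weight = (g.T @ self._cols).reshape(self.weight.shape)
        self.d_bias = g.sum(axis=0)
        # dX = same-conv of grad_out with flipped kernels, in/out channels swapped
        w_flip = self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols_g = _im2col(grad_out, k, k // 2)
        dx = cols_g @ w_flip.reshape(self.in_channels, -1).T
        self._cols = None
        return dx.reshape(n, h, w, self.in_channels).transpose(0, 3, 1, 2).astype(np.float32)


class MaxPool2D(Layer):
    """2x2 stride-2 max pooling; requires even spatial dimensions."""

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        patches = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = patches.reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, hh, ww = grad_out.shape
        flat = np.zeros((n, c, hh, ww, 4), dtype=grad_out.dtype)
        np.put_along_axis(flat, self._argmax[..., None], grad_out[..., None], axis=-1)
        dx = flat.reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._argmax = None
        return dx.reshape(self._in_shape)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        dx = grad_out * self._mask
        self._mask = None
        return dx


class Flatten(Layer):
    def __init__(self) -> None:
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected layer with bias; He-normal initialization."""

    param_names = ("weight", "bias")

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = rng.standard_normal(
            (in_features, out_features), dtype=np.float32
        ) * np.float32(np.sqrt(2.0 / in_features))
        self.bias = np.zeros(out_features, dtype=np.float32)
        self.d_weight = np.zeros_like(self.weight)
        self.d_bias = np.zeros_like(self.bias)
        self._x: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight + self.bias

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.d_weight = self._x.T @ grad_out
        self.d_bias = grad_out.sum(axis=0)
        dx = grad_out @ self.weight.T
        self._x = None
        return dx
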