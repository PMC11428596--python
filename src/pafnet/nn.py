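"""Self-contained numpy engine for small 1D convolutional networks.

Implements exactly the layer vocabulary the classifier architecture needs
— 1D convolution (stride 1, 'same' padding), batch normalization, ReLU,
length-2 max pooling with ceil rounding, flatten, dense, inverted dropout
and sigmoid — with reverse-mode gradients, the Adam optimizer and binary
cross-entropy. Convolutions are evaluated as im2col + matrix products so
that all heavy lifting lands in BLAS.

Conventions: convolutional activations are (batch, channels, length);
dense activations are (batch, features). Parameters default to float32;
float64 is available for gradient checking.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter", "Layer", "Conv1D", "BatchNorm", "ReLU", "MaxPool1D",
    "Flatten", "Dense", "Dropout", "Sigmoid", "Sequential", "Adam",
    "bce_loss", "bce_grad",
]


class Parameter:
    """A trainable (or tracked) array with its gradient."""

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base layer: forward caches whatever backward needs."""

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv1D(Layer):
    """1D convolution, stride 1, 'same' zero padding, optional bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True, dtype=np.float32):
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel
        fan_in, fan_out = in_channels * kernel, out_channels * kernel
        self.w = Parameter(_glorot_uniform(rng, (out_channels, in_channels * kernel),
                                           fan_in, fan_out, dtype))
        self.b = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        # 'same' for stride 1: total pad = kernel-1, split left-light
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def params(self) -> list[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)  # (B,C,L,k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * L, C * self.kernel)
        y = cols @ self.w.value.T
        if self.b is not None:
            y += self.b.value
        self._cols, self._shape = cols, (B, C, L)
        return y.reshape(B, L, self.out_channels).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(B * L, self.out_channels)
        self.w.grad = g2.T @ self._cols
        if self.b is not None:
            self.b.grad = g2.sum(axis=0)
        gcols = (g2 @ self.w.value).reshape(B, L, C, self.kernel).transpose(0, 2, 1, 3)
        gxp = np.zeros((B, C, L + self.kernel - 1), dtype=grad.dtype)
        for j in range(self.kernel):
            gxp[:, :, j : j + L] += gcols[:, :, :, j]
        return gxp[:, :, self.pad_left : self.pad_left + L]


class BatchNorm(Layer):
    """Batch normalization over the batch (and length, for conv inputs).

    Carries four arrays per feature: trainable scale/shift plus running
    mean/variance used at inference. Defaults follow common deep-learning
    practice: eps 1e-3, running-stat momentum 0.9.
    """

    def __init__(self, n_features: int, eps: float = 1e-3, momentum: float = 0.9,
                 dtype=np.float32):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(n_features, dtype=dtype))
        self.beta = Parameter(np.zeros(n_features, dtype=dtype))
        self.running_mean = Parameter(np.zeros(n_features, dtype=dtype), trainable=False)
        self.running_var = Parameter(np.ones(n_features, dtype=dtype), trainable=False)
        # raw exponential moving averages; the running_* parameters hold
        # their bias-corrected values so that inference is usable after
        # few updates and checkpoints need no extra state
        self._ema_mean = np.zeros(n_features, dtype=np.float64)
        self._ema_var = np.zeros(n_features, dtype=np.float64)
        self._updates = 0

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def _bshape(self, x: np.ndarray) -> tuple[int, ...]:
        return (1, -1, 1) if x.ndim == 3 else (1, -1)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2) if x.ndim == 3 else (0,)
        bs = self._bshape(x)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self._updates += 1
            self._ema_mean = m * self._ema_mean + (1 - m) * mu
            self._ema_var = m * self._ema_var + (1 - m) * var
            debias = 1.0 - m ** self._updates
            if debias > 0:  # momentum 1.0 freezes the running statistics
                self.running_mean.value = (self._ema_mean / debias).astype(
                    self.running_mean.value.dtype)
                self.running_var.value = (self._ema_var / debias).astype(
                    self.running_var.value.dtype)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu.reshape(bs)) * inv.reshape(bs)
            self._cache = (xhat, inv, axes, x.shape)
        else:
            inv = 1.0 / np.sqrt(self.running_var.value + self.eps)
            xhat = (x - self.running_mean.value.reshape(bs)) * inv.reshape(bs)
        return self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape = self._cache
        bs = self._bshape(grad)
        m = np.prod([shape[a] for a in axes])
        self.gamma.grad = (grad * xhat).sum(axis=axes)
        self.beta.grad = grad.sum(axis=axes)
        gxhat = grad * self.gamma.value.reshape(bs)
        # standard batchnorm backward, vectorized over features
        t1 = gxhat - gxhat.mean(axis=axes).reshape(bs)
        t2 = xhat * (gxhat * xhat).mean(axis=axes).reshape(bs)
        return inv.reshape(bs) * (t1 - t2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1D(Layer):
    """Length-2 max pooling with ceil rounding (odd tails are kept)."""

    def __init__(self, size: int = 2):
        if size != 2:
            raise ValueError("only pool size 2 is supported")
        self.size = size

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        self._in_len = L
        if L % 2:
            pad = np.full((B, C, 1), -np.inf, dtype=x.dtype)
            x = np.concatenate([x, pad], axis=2)
        xr = x.reshape(B, C, -1, 2)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, Lo = grad.shape
        gx = np.zeros((B, C, Lo, 2), dtype=grad.dtype)
        np.put_along_axis(gx, self._arg[..., None], grad[..., None], axis=3)
        return gx.reshape(B, C, 2 * Lo)[:, :, : self._in_len]


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.w = Parameter(_glorot_uniform(rng, (out_features, in_features),
                                           in_features, out_features, dtype))
        self.b = Parameter(np.zeros(out_features, dtype=dtype))

    def params(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad = grad.T @ self._x
        self.b.grad = grad.sum(axis=0)
        return grad @ self.w.value


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(x.dtype) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60))),
                           np.exp(np.clip(x, -60, 60)) / (1.0 + np.exp(np.clip(x, -60, 60))))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class Sequential:
    """A plain layer stack with reverse-mode differentiation."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.value.shape} vs {a.shape}")
            p.value = a.astype(p.value.dtype)


class Adam:
    """Adam with bias correction (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)


_EPS = 1e-7


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy between probabilities and 0/1 labels."""
    pc = np.clip(p, _EPS, 1 - _EPS)
    return float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))


def bce_grad(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient of mean BCE with respect to the probabilities."""
    pc = np.clip(p, _EPS, 1 - _EPS)
    return ((pc - y) / (pc * (1 - pc))) / p.shape[0]
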