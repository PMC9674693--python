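"""Layers with explicit forward/backward passes.

Each layer caches what it needs during ``forward`` and returns input
gradients from ``backward``.  Trainable layers expose ``params`` and
``grads`` dicts holding references updated in place by the optimizer.
"""

from __future__ import annotations

import numpy as np


def xavier_normal(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


def _bias(rng, kind: str, shape, fan_in: int, fan_out: int) -> np.ndarray:
    if kind == "zeros":
        return np.zeros(shape)
    if kind == "xavier":
        return xavier_normal(rng, shape, fan_in, fan_out)
    raise ValueError(f"unknown bias_init {kind!r}")


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def init(self, rng: np.random.Generator, in_shape):  # returns out_shape
        return in_shape

    def forward(self, x, train: bool, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    @property
    def decayable(self):
        """Parameter names subject to L2 weight decay."""
        return list(self.params)


class Conv1D(Layer):
    """Dilated 1D convolution, 'same' zero padding, channels-last."""

    def __init__(self, out_channels: int, kernel: int = 3, dilation: int = 1, bias_init: str = "zeros"):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("odd kernel sizes only")
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        self.bias_init = bias_init

    def init(self, rng, in_shape):
        length, in_ch = in_shape
        fan_in = in_ch * self.kernel
        fan_out = self.out_channels * self.kernel
        self.params["W"] = xavier_normal(rng, (self.kernel, in_ch, self.out_channels), fan_in, fan_out)
        self.params["b"] = _bias(rng, self.bias_init, (self.out_channels,), fan_in, fan_out)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.in_ch = in_ch
        return (length, self.out_channels)

    def forward(self, x, train, rng=None):
        B, L, C = x.shape
        D = self.dilation * (self.kernel // 2)
        xp = np.zeros((B, L + 2 * D, C), dtype=x.dtype)
        xp[:, D : D + L] = x
        self._xp = xp
        self._L = L
        W = self.params["W"]
        y = np.empty((B, L, self.out_channels), dtype=x.dtype)
        y[:] = self.params["b"]
        for k in range(self.kernel):
            off = k * self.dilation
            seg = xp[:, off : off + L]
            y += (seg.reshape(B * L, C) @ W[k]).reshape(B, L, -1)
        return y

    def backward(self, dy):
        B, L, F = dy.shape
        W = self.params["W"]
        xp = self._xp
        dxp = np.zeros_like(xp)
        dyf = dy.reshape(B * L, F)
        for k in range(self.kernel):
            off = k * self.dilation
            seg = xp[:, off : off + L].reshape(B * L, -1)
            self.grads["W"][k] = seg.T @ dyf
            dxp[:, off : off + L] += (dyf @ W[k].T).reshape(B, L, -1)
        self.grads["b"][:] = dyf.sum(axis=0)
        D = self.dilation * (self.kernel // 2)
        self._xp = None
        return dxp[:, D : D + L]


class Conv2D(Layer):
    """Dilated 2D convolution, square odd kernel, 'same' zero padding."""

    def __init__(self, out_channels: int, kernel: int = 3, dilation: int = 1, bias_init: str = "zeros"):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("odd kernel sizes only")
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        self.bias_init = bias_init

    def init(self, rng, in_shape):
        H, Wd, in_ch = in_shape
        fan_in = in_ch * self.kernel**2
        fan_out = self.out_channels * self.kernel**2
        self.params["W"] = xavier_normal(
            rng, (self.kernel, self.kernel, in_ch, self.out_channels), fan_in, fan_out
        )
        self.params["b"] = _bias(rng, self.bias_init, (self.out_channels,), fan_in, fan_out)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        return (H, Wd, self.out_channels)

    def forward(self, x, train, rng=None):
        B, H, Wd, C = x.shape
        D = self.dilation * (self.kernel // 2)
        xp = np.zeros((B, H + 2 * D, Wd + 2 * D, C), dtype=x.dtype)
        xp[:, D : D + H, D : D + Wd] = x
        self._xp = xp
        W = self.params["W"]
        y = np.empty((B, H, Wd, self.out_channels), dtype=x.dtype)
        y[:] = self.params["b"]
        for i in range(self.kernel):
            for j in range(self.kernel):
                oi, oj = i * self.dilation, j * self.dilation
                seg = xp[:, oi : oi + H, oj : oj + Wd]
                y += (seg.reshape(-1, C) @ W[i, j]).reshape(B, H, Wd, -1)
        return y

    def backward(self, dy):
        B, H, Wd, F = dy.shape
        W = self.params["W"]
        xp = self._xp
        dxp = np.zeros_like(xp)
        dyf = dy.reshape(-1, F)
        for i in range(self.kernel):
            for j in range(self.kernel):
                oi, oj = i * self.dilation, j * self.dilation
                seg = xp[:, oi : oi + H, oj : oj + Wd].reshape(-1, xp.shape[-1])
                self.grads["W"][i, j] = seg.T @ dyf
                dxp[:, oi : oi + H, oj : oj + Wd] += (dyf @ W[i, j].T).reshape(B, H, Wd, -1)
        self.grads["b"][:] = dyf.sum(axis=0)
        D = self.dilation * (self.kernel // 2)
        self._xp = None
        return dxp[:, D : D + H, D : D + Wd]


class MaxPool1D(Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def init(self, rng, in_shape):
        L, C = in_shape
        return (L // self.size, C)

    def forward(self, x, train, rng=None):
        B, L, C = x.shape
        Lo = L // self.size
        v = x[:, : Lo * self.size].reshape(B, Lo, self.size, C)
        self._arg = v.argmax(axis=2)
        self._in_len = L
        return v.max(axis=2)

    def backward(self, dy):
        B, Lo, C = dy.shape
        dv = np.zeros((B, Lo, self.size, C), dtype=dy.dtype)
        np.put_along_axis(dv, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, self._in_len, C), dtype=dy.dtype)
        dx[:, : Lo * self.size] = dv.reshape(B, Lo * self.size, C)
        return dx


class MaxPool2D(Layer):
    def __init__(self, size=(2, 2)):
        super().__init__()
        self.size = tuple(size)

    def init(self, rng, in_shape):
        H, W, C = in_shape
        return (H // self.size[0], W // self.size[1], C)

    def forward(self, x, train, rng=None):
        B, H, W, C = x.shape
        sh, sw = self.size
        Ho, Wo = H // sh, W // sw
        v = x[:, : Ho * sh, : Wo * sw].reshape(B, Ho, sh, Wo, sw, C)
        v = v.transpose(0, 1, 3, 5, 2, 4).reshape(B, Ho, Wo, C, sh * sw)
        self._arg = v.argmax(axis=-1)
        self._in_hw = (H, W)
        return v.max(axis=-1)

    def backward(self, dy):
        B, Ho, Wo, C = dy.shape
        sh, sw = self.size
        dv = np.zeros((B, Ho, Wo, C, sh * sw), dtype=dy.dtype)
        np.put_along_axis(dv, self._arg[..., None], dy[..., None], axis=-1)
        dv = dv.reshape(B, Ho, Wo, C, sh, sw).transpose(0, 1, 4, 2, 5, 3)
        H, W = self._in_hw
        dx = np.zeros((B, H, W, C), dtype=dy.dtype)
        dx[:, : Ho * sh, : Wo * sw] = dv.reshape(B, Ho * sh, Wo * sw, C)
        return dx


class Upsample1D(Layer):
    """Nearest-neighbour repetition along the length axis."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def init(self, rng, in_shape):
        L, C = in_shape
        return (L * self.factor, C)

    def forward(self, x, train, rng=None):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, dy):
        B, L, C = dy.shape
        return dy.reshape(B, L // self.factor, self.factor, C).sum(axis=2)


class Dense(Layer):
    def __init__(self, out_dim: int, bias_init: str = "zeros"):
        super().__init__()
        self.out_dim = out_dim
        self.bias_init = bias_init

    def init(self, rng, in_shape):
        (in_dim,) = in_shape
        self.params["W"] = xavier_normal(rng, (in_dim, self.out_dim), in_dim, self.out_dim)
        self.params["b"] = _bias(rng, self.bias_init, (self.out_dim,), in_dim, self.out_dim)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        return (self.out_dim,)

    def forward(self, x, train, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"][:] = self._x.T @ dy
        self.grads["b"][:] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


class Flatten(Layer):
    def init(self, rng, in_shape):
        self._in_shape = tuple(in_shape)
        return (int(np.prod(in_shape)),)

    def forward(self, x, train, rng=None):
        self._batch_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._batch_shape)


class Reshape(Layer):
    def __init__(self, target):
        super().__init__()
        self.target = tuple(target)

    def init(self, rng, in_shape):
        if int(np.prod(in_shape)) != int(np.prod(self.target)):
            raise ValueError(f"cannot reshape {in_shape} to {self.target}")
        return self.target

    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dy):
        return dy.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class BatchNorm(Layer):
    """Normalizes over all axes but the last (channel) axis."""

    def __init__(self, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps

    def init(self, rng, in_shape):
        C = in_shape[-1]
        self.params["gamma"] = np.ones(C)
        self.params["beta"] = np.zeros(C)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(C)
        self.running_var = np.ones(C)
        self.accumulating = False
        self._acc = None
        return in_shape

    @property
    def decayable(self):
        return []  # scale/shift are not weight-decayed

    def start_accumulation(self):
        """Begin collecting exact activation moments (BN recalibration)."""
        self.accumulating = True
        self._acc = {"n": 0, "mean": 0.0, "var": 0.0}

    def finish_accumulation(self):
        if self._acc and self._acc["n"]:
            self.running_mean = self._acc["mean"] / self._acc["n"]
            self.running_var = self._acc["var"] / self._acc["n"]
        self.accumulating = False
        self._acc = None

    def forward(self, x, train, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self.accumulating:
                n = x.size // x.shape[-1]
                self._acc["n"] += n
                self._acc["mean"] = self._acc["mean"] + n * mean
                self._acc["var"] = self._acc["var"] + n * var
            else:
                self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
                self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._n = x.size // x.shape[-1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat, std, axes, n = self._xhat, self._std, self._axes, self._n
        self.grads["gamma"][:] = (dy * xhat).sum(axis=axes)
        self.grads["beta"][:] = dy.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) / std
        self._xhat = None
        return dx
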