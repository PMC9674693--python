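"""Sequential container, Adam optimizer and the training loop."""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Layer


class Sequential:
    """An ordered stack of layers with a fixed input shape.

    All randomness (weight init, dropout masks, batch shuffling) flows from
    NumPy generators seeded by the caller, so runs are bit-reproducible.
    """

    def __init__(self, layers: list[Layer], input_shape, seed: int = 0, dtype=np.float64):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.init(rng, shape)
            for name in layer.params:
                layer.params[name] = layer.params[name].astype(self.dtype)
                layer.grads[name] = layer.grads[name].astype(self.dtype)
            if isinstance(layer, BatchNorm):
                layer.running_mean = layer.running_mean.astype(self.dtype)
                layer.running_var = layer.running_var.astype(self.dtype)
        self.output_shape = shape

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def param_items(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{li}.{name}", layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[n].size for _, layer, n in self.param_items())


class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, net: Sequential, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {key: np.zeros_like(layer.params[name]) for key, layer, name in net.param_items()}
        self.v = {key: np.zeros_like(layer.params[name]) for key, layer, name in net.param_items()}

    def step(self, l2: float = 0.0):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, name in self.net.param_items():
            g = layer.grads[name]
            if l2 and name in layer.decayable:
                g = g + l2 * layer.params[name]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mae_loss(pred, target):
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def mse_loss(pred, target):
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def bce_loss(pred, target, eps: float = 1e-7):
    p = np.clip(pred, eps, 1 - eps)
    loss = float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))
    grad = (p - target) / (p * (1 - p)) / target.size
    return loss, grad


_LOSSES = {"mae": mae_loss, "mse": mse_loss, "bce": bce_loss}


def fit(
    net: Sequential,
    inputs: np.ndarray,
    targets: np.ndarray,
    *,
    loss: str,
    epochs: int,
    lr: float,
    batch_size: int,
    seed: int = 0,
    l2: float = 0.0,
    input_noise_sd: float = 0.0,
) -> list[float]:
    """Mini-batch training; returns the per-epoch mean loss history.

    ``input_noise_sd`` corrupts each batch input with fresh zero-mean Gaussian
    noise (the denoising-autoencoder corruption); targets are untouched.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    loss_fn = _LOSSES[loss]
    opt = Adam(net, lr=lr)
    rng = np.random.default_rng(seed)
    inputs = np.asarray(inputs, dtype=net.dtype)
    targets = np.asarray(targets, dtype=net.dtype)
    n = inputs.shape[0]
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = inputs[idx]
            if input_noise_sd > 0:
                xb = xb + rng.normal(0.0, input_noise_sd, size=xb.shape).astype(inputs.dtype)
            pred = net.forward(xb, train=True, rng=rng)
            value, grad = loss_fn(pred, targets[idx])
            net.backward(grad.astype(net.dtype))
            opt.step(l2=l2)
            total += value * len(idx)
        history.append(total / n)
    _recalibrate_batchnorm(net, inputs, batch_size)
    return history


def _recalibrate_batchnorm(net: Sequential, inputs: np.ndarray, batch_size: int) -> None:
    """Set batch-norm running moments from a pass with the final weights.

    During training the running statistics lag the weights; with few
    optimizer steps the lag is large enough to hurt inference.  One
    forward sweep (dropout off, batch statistics active and accumulated)
    pins the inference-time moments to the trained network.
    """
    bn_layers = [l for l in net.layers if isinstance(l, BatchNorm)]
    if not bn_layers:
        return
    for layer in bn_layers:
        layer.start_accumulation()
    drop = [l for l in net.layers if hasattr(l, "rate")]
    rates = [(l, l.rate) for l in drop]
    for l in drop:
        l.rate = 0.0
    try:
        for start in range(0, inputs.shape[0], batch_size):
            net.forward(inputs[start : start + batch_size], train=True)
    finally:
        for l, r in rates:
            l.rate = r
        for layer in bn_layers:
            layer.finish_accumulation()
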