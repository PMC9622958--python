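"""Minimal 1-D convolutional network engine (NumPy, CPU).

Implements exactly the layers the residual PPG classifier needs -- 1-D
convolution with same-length padding, batch normalization, ReLU, max
pooling, dense layers, dropout -- together with reverse-mode gradients, the
Adam optimizer, and a softmax cross-entropy loss.  Arrays are float32 in
``(batch, channels, length)`` layout.  All randomness flows through a
caller-supplied :class:`numpy.random.Generator`, so training is bitwise
reproducible on a fixed seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

F32 = np.float32


def glorot_uniform(shape: Tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    """Base layer: ``params``/``grads`` are dicts of same-keyed arrays."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1DSame(Layer):
    """1-D convolution, stride 1, zero 'same' padding, odd kernel width."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd for same-length padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.params["W"] = glorot_uniform((c_out, c_in, kernel),
                                          fan_in=c_in * kernel,
                                          fan_out=c_out * kernel, rng=rng)
        self.params["b"] = np.zeros(c_out, dtype=F32)
        self._xp: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        B, C, L = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        y = np.zeros((B, self.c_out, L), dtype=F32)
        for j in range(self.kernel):
            # (F,C) x (B,C,L) -> (F,B,L)
            y += np.tensordot(W[:, :, j], xp[:, :, j:j + L], axes=(1, 1)).transpose(1, 0, 2)
        y += b[None, :, None]
        if training:
            self._xp = xp
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        xp = self._xp
        B, F, L = gy.shape
        p = self.kernel // 2
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for j in range(self.kernel):
            dW[:, :, j] = np.tensordot(gy, xp[:, :, j:j + L], axes=([0, 2], [0, 2]))
            # (C,F) x (B,F,L) -> (C,B,L)
            dxp[:, :, j:j + L] += np.tensordot(W[:, :, j], gy, axes=(0, 1)).transpose(1, 0, 2)
        self.grads["W"] = dW
        self.grads["b"] = gy.sum(axis=(0, 2))
        self._xp = None
        return dxp[:, :, p:p + L]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.99):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=F32)
        self.params["beta"] = np.zeros(channels, dtype=F32)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        g, b = self.params["gamma"], self.params["beta"]
        if training:
            n = x.shape[0] * x.shape[2]
            mean = x.sum(axis=(0, 2)) / n
            # single-pass second moment keeps the big array traffic down
            var = np.einsum("bcl,bcl->c", x, x) / n - mean * mean
            np.maximum(var, 0.0, out=var)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        if training:
            self._cache = (xhat, inv_std)
        return (g[None, :, None] * xhat + b[None, :, None]).astype(F32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        g = self.params["gamma"]
        B, C, L = gy.shape
        n = B * L
        self.grads["gamma"] = (gy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = gy.sum(axis=(0, 2))
        dxhat = gy * g[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dx = (inv_std[None, :, None] / n) * (n * dxhat - s1 - xhat * s2)
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._mask
        self._mask = None
        return g


class MaxPool1D(Layer):
    """Max pooling, non-overlapping windows (stride = size); truncates remainder."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, L = x.shape
        n = L // self.size
        xr = x[:, :, : n * self.size].reshape(B, C, n, self.size)
        if self.size == 2:
            a, b = xr[..., 0], xr[..., 1]
            mask = a >= b  # ties go to the left element
            y = np.where(mask, a, b)
            if training:
                self._mask, self._shape = mask, x.shape
            return y
        idx = xr.argmax(axis=3)
        y = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
        if training:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        n = L // self.size
        gxr = np.zeros((B, C, n, self.size), dtype=gy.dtype)
        if self.size == 2:
            gxr[..., 0] = np.where(self._mask, gy, 0)
            gxr[..., 1] = np.where(self._mask, 0, gy)
            self._mask = None
        else:
            np.put_along_axis(gxr, self._idx[..., None], gy[..., None], axis=3)
            self._idx = None
        gx = np.zeros((B, C, L), dtype=gy.dtype)
        gx[:, :, : n * self.size] = gxr.reshape(B, C, n * self.size)
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = glorot_uniform((n_in, n_out), n_in, n_out, rng)
        self.params["b"] = np.zeros(n_out, dtype=F32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        gx = gy @ self.params["W"].T
        self._x = None
        return gx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        g = gy * self._mask
        self._mask = None
        return g


class IdentityBlock:
    """Residual unit: x + ReLU(BN(conv(ReLU(BN(conv(x)))))).

    Both convolutions preserve channel count and length, so the shortcut is
    a pure elementwise sum (no projection); the sum is applied after the
    final ReLU of the convolutional branch.
    """

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.conv1 = Conv1DSame(channels, channels, kernel, rng)
        self.bn1 = BatchNorm1D(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1DSame(channels, channels, kernel, rng)
        self.bn2 = BatchNorm1D(channels)
        self.relu2 = ReLU()

    @property
    def layers(self) -> List[Layer]:
        return [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        a = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        b = self.relu2.forward(self.bn2.forward(self.conv2.forward(a, training), training), training)
        return x + b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(gy)
        g = self.bn2.backward(g)
        g = self.conv2.backward(g)
        g = self.relu1.backward(g)
        g = self.bn1.backward(g)
        g = self.conv1.backward(g)
        return gy + g


class ResNet1D:
    """The 1-D residual classifier network.

    input -> conv(F, k, same) -> max-pool -> [identity block -> max-pool] x B
    -> flatten -> dense(D) -> ReLU -> dropout -> dense(2) logits.
    Softmax is applied by the loss / ``predict_proba``.
    """

    def __init__(
        self,
        input_length: int,
        n_identity_blocks: int = 8,
        n_filters: int = 40,
        kernel_width: int = 3,
        dense_units: int = 100,
        dropout_rate: float = 0.2,
        pool_size: int = 2,
        n_classes: int = 2,
        rng: Optional[np.random.Generator] = None,
    ):
        if input_length < pool_size ** (n_identity_blocks + 1):
            raise ValueError(
                f"input_length={input_length} too short for "
                f"{n_identity_blocks + 1} pools of size {pool_size}"
            )
        rng = rng or np.random.default_rng(0)
        self.cfg = dict(input_length=input_length,
                        n_identity_blocks=n_identity_blocks,
                        n_filters=n_filters, kernel_width=kernel_width,
                        dense_units=dense_units, dropout_rate=dropout_rate,
                        pool_size=pool_size, n_classes=n_classes)
        self.conv0 = Conv1DSame(1, n_filters, kernel_width, rng)
        self.pool0 = MaxPool1D(pool_size)
        self.blocks: List[IdentityBlock] = []
        self.pools: List[MaxPool1D] = []
        length = input_length // pool_size
        for _ in range(n_identity_blocks):
            self.blocks.append(IdentityBlock(n_filters, kernel_width, rng))
            self.pools.append(MaxPool1D(pool_size))
            length //= pool_size
        self.final_length = length
        self.flatten = Flatten()
        self.dense1 = Dense(n_filters * length, dense_units, rng)
        self.relu_d = ReLU()
        self.dropout = Dropout(dropout_rate, rng)
        self.dense2 = Dense(dense_units, n_classes, rng)

    # -- parameter bookkeeping ------------------------------------------
    @property
    def param_layers(self) -> List[Layer]:
        layers: List[Layer] = [self.conv0]
        for blk in self.blocks:
            layers.extend([blk.conv1, blk.bn1, blk.conv2, blk.bn2])
        layers.extend([self.dense1, self.dense2])
        return layers

    def parameters(self) -> List[Tuple[Layer, str]]:
        return [(layer, name) for layer in self.param_layers for name in layer.params]

    def n_parameters(self) -> int:
        """Total trainable parameter count."""
        return int(sum(layer.params[name].size for layer, name in self.parameters()))

    def get_weights(self) -> List[np.ndarray]:
        ws = [layer.params[name].copy() for layer, name in self.parameters()]
        for layer in self.param_layers:
            if isinstance(layer, BatchNorm1D):
                ws.append(layer.running_mean.copy())
                ws.append(layer.running_var.copy())
        return ws

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for layer, name in self.parameters():
            layer.params[name] = next(it).copy()
        for layer in self.param_layers:
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map ``(B, L)`` or ``(B, 1, L)`` inputs to ``(B, n_classes)`` logits."""
        x = np.asarray(x, dtype=F32)
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.cfg["input_length"]:
            raise ValueError(
                f"expected input length {self.cfg['input_length']}, got {x.shape[2]}"
            )
        h = self.pool0.forward(self.conv0.forward(x, training), training)
        for blk, pool in zip(self.blocks, self.pools):
            h = pool.forward(blk.forward(h, training), training)
        h = self.flatten.forward(h, training)
        h = self.relu_d.forward(self.dense1.forward(h, training), training)
        h = self.dropout.forward(h, training)
        return self.dense2.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.dense2.backward(dlogits)
        g = self.dropout.backward(g)
        g = self.relu_d.backward(g)
        g = self.dense1.backward(g)
        g = self.flatten.backward(g)
        for blk, pool in zip(reversed(self.blocks), reversed(self.pools)):
            g = pool.backward(g)
            g = blk.backward(g)
        g = self.pool0.backward(g)
        self.conv0.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities in evaluation mode (running BN statistics)."""
        x = np.asarray(x, dtype=F32)
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i:i + batch_size], training=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits.

    With two classes this equals binary cross-entropy on the positive-class
    probability.
    """
    p = softmax(logits.astype(np.float64))
    B = logits.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(B), y] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return loss, (dlogits / B).astype(F32)


class Adam:
    """Adam optimizer over a network's (layer, name) parameter list."""

    def __init__(self, params: List[Tuple[Layer, str]], lr: float = 1e-6,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in params]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, (layer, name) in enumerate(self.params):
            g = layer.grads[name]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            layer.params[name] = (layer.params[name]
                                  - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
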