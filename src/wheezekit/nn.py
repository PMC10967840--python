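"""Compact numpy neural-network backend for the 2D wheeze classifier.

Implements exactly the layers the classifier needs — valid (unpadded) 3x3
convolution, 2x2 max pooling with floor division, inverted dropout, dense
layers, ReLU — plus Adam and a numerically stable binary cross-entropy on
logits.  Convolutions run as im2col + BLAS matmul in float32; everything is
driven by an explicit numpy Generator, so training is bit-reproducible for
a fixed seed on a given BLAS.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class ShapeError(ValueError):
    """Raised when an input cannot survive the layer stack."""


def conv2d_output_shape(h: int, w: int, kernel: tuple[int, int]) -> tuple[int, int]:
    return h - kernel[0] + 1, w - kernel[1] + 1


def pool2d_output_shape(h: int, w: int, pool: tuple[int, int]) -> tuple[int, int]:
    return h // pool[0], w // pool[1]


class Layer:
    trainable = False

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def params(self):
        return []

    def grads(self):
        return []


class Conv2D(Layer):
    """Valid-mode 2D convolution (cross-correlation), NCHW layout."""

    trainable = True

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], rng: np.random.Generator,
                 needs_input_grad: bool = True):
        kh, kw = kernel
        self.needs_input_grad = needs_input_grad
        fan_in = in_channels * kh * kw
        scale = np.sqrt(2.0 / fan_in)   # He init for ReLU stacks
        self.w = (scale * rng.standard_normal(
            (out_channels, in_channels, kh, kw))).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.kernel = kernel
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        kh, kw = self.kernel
        if h < kh or w < kw:
            raise ShapeError(
                f"Conv2D: input {h}x{w} smaller than kernel {kh}x{kw}")
        windows = sliding_window_view(x, (kh, kw), axis=(2, 3))
        # (n, c, ho, wo, kh, kw) -> (n*ho*wo, c*kh*kw)
        ho, wo = windows.shape[2], windows.shape[3]
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
        self._cols = cols
        self._in_shape = x.shape
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wmat.T + self.b
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, f, ho, wo = grad.shape
        _, c, h, w = self._in_shape
        kh, kw = self.kernel
        gmat = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
        self.dw = (gmat.T @ self._cols).reshape(self.w.shape)
        self.db = gmat.sum(axis=0)
        if not self.needs_input_grad:   # first layer: dX is never consumed
            return None
        # dX = full correlation of grad with flipped kernels
        padded = np.zeros((n, f, ho + 2 * (kh - 1), wo + 2 * (kw - 1)),
                          dtype=grad.dtype)
        padded[:, :, kh - 1:kh - 1 + ho, kw - 1:kw - 1 + wo] = grad
        windows = sliding_window_view(padded, (kh, kw), axis=(2, 3))
        colsg = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, f * kh * kw)
        wflip = self.w[:, :, ::-1, ::-1].transpose(0, 2, 3, 1).reshape(f * kh * kw, c)
        dx = (colsg @ wflip).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 (or general) max pooling with floor division; odd edges cropped."""

    def __init__(self, pool: tuple[int, int] = (2, 2)):
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        ph, pw = self.pool
        ho, wo = h // ph, w // pw
        if ho < 1 or wo < 1:
            raise ShapeError(f"MaxPool2D: input {h}x{w} smaller than pool {ph}x{pw}")
        cropped = x[:, :, :ho * ph, :wo * pw]
        windows = np.ascontiguousarray(
            cropped.reshape(n, c, ho, ph, wo, pw).transpose(0, 1, 2, 4, 3, 5)
        ).reshape(n, c, ho, wo, ph * pw)
        self._argmax = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, self._argmax[..., None], axis=-1)[..., 0]
        self._in_shape = (n, c, h, w)
        return out

    def backward(self, grad):
        n, c, h, w = self._in_shape
        ph, pw = self.pool
        ho, wo = h // ph, w // pw
        flat = np.zeros((n, c, ho, wo, ph * pw), dtype=grad.dtype)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        dx[:, :, :ho * ph, :wo * pw] = flat.reshape(
            n, c, ho, wo, ph, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho * ph, wo * pw)
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.w = (scale * rng.standard_normal(
            (in_features, out_features))).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights):
            p[...] = w

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params()))


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, learning_rate: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2 ** self.t) / (1 - self.beta1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy on logits and its gradient w.r.t. logits."""
    z = logits.astype(np.float64).ravel()
    y = targets.astype(np.float64).ravel()
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = ((sigmoid(z) - y) / z.size).astype(np.float32).reshape(logits.shape)
    return float(loss), grad


@dataclass
class TrainHistory:
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    stopped_epoch: int


def fit(model: Sequential, x_train, y_train, x_val, y_val, *,
        learning_rate: float = 0.001, batch_size: int = 32,
        max_epochs: int = 100, patience: int = 10, seed: int = 0
        ) -> TrainHistory:
    """Mini-batch Adam with early stopping on validation loss.

    Stops after ``patience`` epochs without a new best validation loss (or at
    ``max_epochs``) and restores the best-validation weights.
    """
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.params(), learning_rate=learning_rate)
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = -1
    history = TrainHistory([], [], -1, -1)
    since_best = 0

    for epoch in range(max_epochs):
        order = rng.permutation(x_train.shape[0])
        epoch_loss = 0.0
        for start in range(0, order.size, batch_size):
            batch = order[start:start + batch_size]
            logits = model.forward(x_train[batch], train=True, rng=rng)
            loss, grad = bce_with_logits(logits, y_train[batch])
            model.backward(grad)
            optimizer.step(model.grads())
            epoch_loss += loss * batch.size
        history.train_loss.append(epoch_loss / order.size)

        val_logits = predict_logits(model, x_val, batch_size)
        val_loss, _ = bce_with_logits(val_logits, y_val)
        history.val_loss.append(val_loss)

        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > patience:
                break

    model.set_weights(best_weights)
    history.best_epoch = best_epoch
    history.stopped_epoch = len(history.val_loss) - 1
    return history


def predict_logits(model: Sequential, x, batch_size: int = 64) -> np.ndarray:
    chunks = [model.forward(x[i:i + batch_size], train=False)
              for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(chunks, axis=0)


def predict_proba(model: Sequential, x, batch_size: int = 64) -> np.ndarray:
    return sigmoid(predict_logits(model, x, batch_size)).ravel()


def clone_weights(model: Sequential):
    return copy.deepcopy(model.get_weights())
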