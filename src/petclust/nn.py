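"""Minimal NumPy building blocks for small convolutional networks.

Self-contained forward/backward implementations of the handful of layers
the autoencoder needs: 3x3 same-padded convolution (im2col + BLAS matmul),
2x2 max-pooling, 2x2 nearest-neighbor up-sampling, ReLU, sigmoid, and an
Adam optimizer.  Tensors are ``(N, C, H, W)`` float64 throughout; gradients
are exact (verified against finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "MaxPool2", "Upsample2", "ReLU", "Adam",
           "sigmoid", "bce_loss_and_grad", "mse_loss_and_grad"]


class Conv2D:
    """3x3 convolution with stride 1 and same (zero) padding."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel: int = 3):
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        # He initialization, appropriate for the ReLU stages
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, in_channels, kernel, kernel))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._win = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) sliding windows over the padded input
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.kernel, self.kernel),
                                                       axis=(2, 3))
        self._win = win
        out = np.tensordot(win, self.W, axes=([1, 4, 5], [1, 2, 3]))  # (N, H, W, O)
        out += self.b
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win = self._win
        N, C, H, W = win.shape[0], win.shape[1], win.shape[2], win.shape[3]
        self.dW[...] = np.tensordot(dout, win, axes=([0, 2, 3], [0, 2, 3]))
        self.db[...] = dout.sum(axis=(0, 2, 3))
        dcol = np.tensordot(dout, self.W, axes=([1], [0]))  # (N, H, W, C, k, k)
        p = self.kernel // 2
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for i in range(self.kernel):
            for j in range(self.kernel):
                dxp[:, :, i:i + H, j:j + W] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:-p, p:-p] if p else dxp


class MaxPool2:
    """2x2 max-pooling; ties route the gradient to the first maximum."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial size ({H}, {W}) not divisible by 2")
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(N, C, H // 2, W // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = (N, C, H, W)
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._in_shape
        dflat = np.zeros((N, C, H // 2, W // 2, 4))
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(N, C, H, W)


class Upsample2:
    """2x2 nearest-neighbor up-sampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = dout.shape
        return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss_and_grad(z: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-pixel binary cross-entropy of sigmoid(z) vs target.

    Takes pre-sigmoid logits for numerical stability; returns the loss and
    the gradient with respect to ``z``.
    """
    y = sigmoid(z)
    eps = 1e-12
    loss = -np.mean(target * np.log(y + eps) + (1.0 - target) * np.log(1.0 - y + eps))
    grad = (y - target) / z.size
    return float(loss), grad


def mse_loss_and_grad(z: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error of sigmoid(z) vs target, gradient w.r.t. ``z``."""
    y = sigmoid(z)
    diff = y - target
    loss = np.mean(diff ** 2)
    grad = 2.0 * diff * y * (1.0 - y) / z.size
    return float(loss), grad


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
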