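"""A small NumPy neural-network engine for the dual-branch affinity model.

Layers implement `forward(x, train)` / `backward(grad)` with float32
activations.  Convolutions are valid (no padding), stride 1, computed as a
sum of kernel-position-shifted GEMMs — no im2col buffer, which keeps memory
flat at batch size 256 on 97x97 inputs.  Max-pooling is 2x2 non-overlapping
with trailing rows/columns cropped (floor semantics).  Dropout is inverted
(scaled at train time, identity at eval).  The optimizer is Adam.

Everything is seeded through numpy Generators, so training runs are exactly
reproducible on a given platform.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class; layers with parameters expose params()/grads() pairs."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """Valid convolution, stride 1, channels-last (B, H, W, C), ReLU optional.

    Weights are He-normal initialized (fan-in = kh*kw*c_in)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.W = (rng.standard_normal((kernel, kernel, c_in, c_out)) * scale).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(B,H,W,C) -> (B*Ho*Wo, kh*kw*C), one contiguous buffer so the
        convolution is a single wide GEMM."""
        kh = self.kernel
        B, H, W, C = x.shape
        Ho, Wo = H - kh + 1, W - kh + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (kh, kh), axis=(1, 2))
        # (B,Ho,Wo,C,kh,kw) -> rows ordered (i,j,c) to match W.reshape below
        return win.transpose(0, 1, 2, 4, 5, 3).reshape(B * Ho * Wo, kh * kh * C)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        kh = self.kernel
        B, H, W, C = x.shape
        Ho, Wo = H - kh + 1, W - kh + 1
        c_out = self.b.size
        cols = self._im2col(x)
        out = cols @ self.W.reshape(kh * kh * C, c_out) + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(B, Ho, Wo, c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols = self._cols
        assert cols is not None, "backward called before forward(train=True)"
        kh = self.kernel
        B, H, W, C = self._xshape
        Ho, Wo = grad.shape[1], grad.shape[2]
        c_out = grad.shape[3]
        gflat = grad.reshape(-1, c_out)
        self.db[...] = gflat.sum(axis=0)
        self.dW[...] = (cols.T @ gflat).reshape(self.dW.shape)
        dcols = (gflat @ self.W.reshape(kh * kh * C, c_out).T).reshape(
            B, Ho, Wo, kh, kh, C
        )
        dx = np.zeros((B, H, W, C), dtype=grad.dtype)
        for i in range(kh):
            for j in range(kh):
                dx[:, i : i + Ho, j : j + Wo, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dx

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 max-pool, stride 2, trailing odd row/column cropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        Ho, Wo = H // 2, W // 2
        xc = x[:, : 2 * Ho, : 2 * Wo, :].reshape(B, Ho, 2, Wo, 2, C)
        out = xc.max(axis=(2, 4))
        if train:
            self._shape = x.shape
            self._mask = xc == out[:, :, None, :, None, :]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        Ho, Wo = H // 2, W // 2
        g = self._mask * grad[:, :, None, :, None, :]
        dx = np.zeros(self._shape, dtype=grad.dtype)
        dx[:, : 2 * Ho, : 2 * Wo, :] = g.reshape(B, 2 * Ho, 2 * Wo, C)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class Dropout(Layer):
    """Inverted dropout: active only at train time, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]


class Adam:
    """Adam optimizer with bias correction; defaults match the training
    protocol (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = params
        self.grads = grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(p.dtype)
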