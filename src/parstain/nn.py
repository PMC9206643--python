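"""Minimal CPU neural-network framework for the colorizer.

Implements exactly what the conditional-GAN colorizer needs — strided
convolutions via im2col, leaky-ReLU / sigmoid nonlinearities, nearest
upsampling, Adam, and binary cross-entropy / L1 losses — with explicit
forward/backward passes on float32 numpy arrays. All tensors are
channels-first ``(N, C, H, W)``. Every layer caches its forward inputs, so
a layer instance must be re-run forward before each backward; gradients
accumulate into ``.grads`` until ``zero_grad``.

Gradient correctness is pinned by finite-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np

#: Parameter and activation dtype. Single precision doubles the effective
#: matmul throughput on CPU and is ample for GAN training.
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Conv2d",
    "LeakyReLU",
    "Sigmoid",
    "UpsampleNearest2",
    "Sequential",
    "Adam",
    "bce_with_logits",
    "l1_loss",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with zero padding.

    Weight shape ``(C_in * k * k, C_out)``; initialization is
    Gaussian(0, 0.02), the conventional conditional-GAN choice.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": rng.normal(0.0, 0.02, (c_in * k * k, c_out)).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        # gather k*k shifted contiguous slabs; col index order matches the
        # (C, k, k) raveling of the weight rows
        cols6 = np.empty((n, ho, wo, c, k, k), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                cols6[:, :, :, :, i, j] = xp[
                    :, :, i : i + s * ho : s, j : j + s * wo : s
                ].transpose(0, 2, 3, 1)
        cols = cols6.reshape(n * ho * wo, c * k * k)
        out = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, x.shape, (ho, wo))
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        dy_flat = np.ascontiguousarray(
            dy.transpose(0, 2, 3, 1), dtype=DTYPE
        ).reshape(-1, self.c_out)
        self.grads["W"] += cols.T @ dy_flat
        self.grads["b"] += dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.params["W"].T).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Layer):
    def __init__(self):
        super().__init__()
        self._out = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = sigmoid(x)
        return self._out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._out * (1.0 - self._out)


class UpsampleNearest2(Layer):
    """Nearest-neighbor 2x upsampling (checkerboard-free alternative to a
    transposed convolution when followed by a conv)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def param_layers(self) -> list[Layer]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.param_layers())
            elif layer.params:
                out.append(layer)
        return out


class Adam:
    """Adaptive-moment optimizer; conditional-GAN defaults lr 2e-4, beta1 0.5."""

    def __init__(self, layers: list[Layer], lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / (1 - self.b1**self.t)
                vhat = self.v[i][k] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(z: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz).

    Numerically stable: BCE = softplus(z) - t*z elementwise.
    """
    sp = np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))), np.log1p(np.exp(z)))
    loss = float(np.mean(sp - target * z))
    grad = (sigmoid(z) - target) / z.size
    return loss, grad


def l1_loss(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error; returns (loss, dloss/da)."""
    diff = a - b
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size
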