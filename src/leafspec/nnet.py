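"""A compact numpy neural-network engine for 1-D spectral regression.

Implements exactly the layer vocabulary the pigment regressors need —
1-D convolution ('same' padding), batch normalization, ReLU, max pooling,
flatten and dense layers — with explicit forward/backward passes and an
Adam optimizer. Every stochastic choice (init, batch order) flows from an
explicit ``numpy.random.Generator``, so training is bit-reproducible.

Gradients with respect to *intermediate activations* are first-class
(`Sequential.backward` returns them layer by layer), which is what the
1-D Grad-CAM++ wavelength-importance maps are built on.
"""

from __future__ import annotations

import numpy as np

from .containers import ParameterError


class Layer:
    """Base layer: forward caches what backward needs; params/grads lists."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """1-D convolution with zero 'same' padding, stride 1.

    Input (N, C_in, L) → output (N, C_out, L). He-initialized.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ParameterError("kernel size must be odd for 'same' padding")
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.W = rng.normal(0.0, scale, (out_channels, in_channels, kernel_size))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel_size = kernel_size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k = self.kernel_size
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # cols: (N, C_in, L, K) sliding windows
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        self._cols = cols
        self._in_shape = x.shape
        return np.einsum("nclk,ock->nol", cols, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        pad = k // 2
        self.dW[...] = np.einsum("nol,nclk->ock", grad_out, self._cols, optimize=True)
        self.db[...] = grad_out.sum(axis=(0, 2))
        n, c, length = self._in_shape
        dxp = np.zeros((n, c, length + 2 * pad))
        for j in range(k):
            dxp[:, :, j : j + length] += np.einsum(
                "nol,oc->ncl", grad_out, self.W[:, :, j], optimize=True
            )
        return dxp[:, :, pad : pad + length]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2) if x.ndim == 3 else (0,)
        shape = (1, -1, 1) if x.ndim == 3 else (1, -1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        self._cache = (xhat, inv_std, axes, shape, train)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape, was_train = self._cache
        self.dgamma[...] = (grad_out * xhat).sum(axis=axes)
        self.dbeta[...] = grad_out.sum(axis=axes)
        dxhat = grad_out * self.gamma.reshape(shape)
        if not was_train:
            return dxhat * inv_std.reshape(shape)
        m = grad_out.size / grad_out.shape[1]  # samples per channel
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        )
        return term * inv_std.reshape(shape)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling (size = stride); trailing remainder dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, length = x.shape
        out_len = length // self.size
        if out_len < 1:
            raise ParameterError(
                f"input length {length} too small for pooling of size {self.size}"
            )
        windows = x[:, :, : out_len * self.size].reshape(n, c, out_len, self.size)
        self._argmax = windows.argmax(axis=3)
        self._in_shape = x.shape
        return windows.max(axis=3)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, length = self._in_shape
        out_len = grad_out.shape[2]
        dx = np.zeros((n, c, out_len, self.size))
        idx_n, idx_c, idx_l = np.meshgrid(
            np.arange(n), np.arange(c), np.arange(out_len), indexing="ij"
        )
        dx[idx_n, idx_c, idx_l, self._argmax] = grad_out
        full = np.zeros((n, c, length))
        full[:, :, : out_len * self.size] = dx.reshape(n, c, out_len * self.size)
        return full


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, scale, (in_features, out_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad_out
        self.db[...] = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Sequential:
    """Ordered layer stack with whole-network forward/backward."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._activations = [x]
        for layer in self.layers:
            x = layer.forward(x, train=train)
            self._activations.append(x)
        return x

    def backward(self, grad_out: np.ndarray, stop_at: int = 0) -> np.ndarray:
        """Backpropagate; returns the gradient at the output of layer
        ``stop_at - 1`` (i.e. the input gradient of layer ``stop_at``)."""
        for layer in reversed(self.layers[stop_at:]):
            grad_out = layer.backward(grad_out)
        return grad_out

    def activation(self, layer_index: int) -> np.ndarray:
        """Output of layer ``layer_index`` from the latest forward pass."""
        return self._activations[layer_index + 1]

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state_dict(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        extra = iter(state[len(params) :])
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)


class Adam:
    """Adam optimizer over a parameter/gradient list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
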