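"""Minimal NumPy layers for small-image CNNs.

Data layout is NHWC (batch, height, width, channels), float64.  Each layer
exposes ``forward(x, train)`` / ``backward(grad)`` plus flat ``params`` and
``grads`` lists consumed by the optimizer.  Convolutions are stride-1,
same-padded, implemented via im2col; pooling layers use window 2, stride 2
with floor semantics on odd dimensions.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: list
    grads: list

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        return in_shape

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv2D(Layer):
    """3x3 (configurable) stride-1 same-padded convolution."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.ksize = ksize
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = ksize * ksize * in_ch
        fan_out = ksize * ksize * out_ch
        self.W = glorot_uniform(rng, (ksize * ksize * in_ch, out_ch), fan_in, fan_out)
        self.b = np.zeros(out_ch)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, pad = self.ksize, self.ksize // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        # (N, H, W, C, k, k) -> (N*H*W, k*k*C) with kernel-major ordering
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        n, h, w, c = x.shape
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * c)
        return cols

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        n, h, w, _ = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        k, pad = self.ksize, self.ksize // 2
        gflat = grad.reshape(n * h * w, self.out_ch)
        self.grads[0][...] = self._cols.T @ gflat
        self.grads[1][...] = gflat.sum(axis=0)
        dcols = (gflat @ self.W.T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pad:pad + h, pad:pad + w, :]

    def out_shape(self, in_shape):
        return (in_shape[0], in_shape[1], self.out_ch)


class BatchNorm(Layer):
    """Per-channel batch normalization with running inference statistics.

    The running mean/variance are exponential moving averages with bias
    correction (as in Adam), so inference statistics are usable after the
    first few updates — important here because small training sets give few
    updates per epoch.
    """

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.zeros(n_ch)
        self.n_updates = 0

    def _inference_stats(self) -> tuple[np.ndarray, np.ndarray]:
        if self.n_updates == 0:
            return np.zeros_like(self.running_mean), np.ones_like(self.running_var)
        correction = 1.0 - self.momentum**self.n_updates
        return self.running_mean / correction, self.running_var / correction

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self.n_updates += 1
            self._xhat = (x - mean) / np.sqrt(var + self.eps)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            return self.gamma * self._xhat + self.beta
        mean, var = self._inference_stats()
        return self.gamma * (x - mean) / np.sqrt(var + self.eps) + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = tuple(range(grad.ndim - 1))
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        return self._istd * (
            dxhat
            - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool2(Layer):
    """2x2 average pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        return xc.mean(axis=(2, 4))

    def backward(self, grad):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, h, w, c))
        g = np.repeat(np.repeat(grad, 2, axis=1), 2, axis=2) / 4.0
        dx[:, : h2 * 2, : w2 * 2, :] = g
        return dx

    def out_shape(self, in_shape):
        return (in_shape[0] // 2, in_shape[1] // 2, in_shape[2])


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, floor semantics.

    Window ties route the gradient to the first maximum (argmax order) so it
    is never duplicated.
    """

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xw = (
            x[:, : h2 * 2, : w2 * 2, :]
            .reshape(n, h2, 2, w2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h2, w2, 4, c)
        )
        self._argmax = xw.argmax(axis=3)
        return xw.max(axis=3)

    def backward(self, grad):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        g = np.zeros((n, h2, w2, 4, c))
        np.put_along_axis(
            g, self._argmax[:, :, :, None, :], grad[:, :, :, None, :], axis=3
        )
        dx = np.zeros((n, h, w, c))
        dx[:, : h2 * 2, : w2 * 2, :] = (
            g.reshape(n, h2, w2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h2 * 2, w2 * 2, c)
        )
        return dx

    def out_shape(self, in_shape):
        return (in_shape[0] // 2, in_shape[1] // 2, in_shape[2])


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._in_shape
        return np.broadcast_to(grad[:, None, None, :], (n, h, w, c)) / (h * w)

    def out_shape(self, in_shape):
        return (in_shape[2],)


class Flatten(Layer):
    def forward(self, x, train):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.W = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim)
        self.b = np.zeros(out_dim)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T

    def out_shape(self, in_shape):
        return (self.W.shape[1],)


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class AvgPool3x3Same(Layer):
    """3x3 stride-1 same-padded average pooling (inception pool branch)."""

    def forward(self, x, train):
        self._in_shape = x.shape
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="edge")
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))
        return win.mean(axis=(4, 5))

    def backward(self, grad):
        n, h, w, c = self._in_shape
        dxp = np.zeros((n, h + 2, w + 2, c))
        for i in range(3):
            for j in range(3):
                dxp[:, i:i + h, j:j + w, :] += grad / 9.0
        dx = dxp[:, 1:1 + h, 1:1 + w, :]
        # edge-padding: fold border contributions back onto the edge pixels
        dx[:, 0, :, :] += dxp[:, 0, 1:1 + w, :]
        dx[:, -1, :, :] += dxp[:, -1, 1:1 + w, :]
        dx[:, :, 0, :] += dxp[:, 1:1 + h, 0, :]
        dx[:, :, -1, :] += dxp[:, 1:1 + h, -1, :]
        dx[:, 0, 0, :] += dxp[:, 0, 0, :]
        dx[:, 0, -1, :] += dxp[:, 0, -1, :]
        dx[:, -1, 0, :] += dxp[:, -1, 0, :]
        dx[:, -1, -1, :] += dxp[:, -1, -1, :]
        return dx


class InceptionBlock(Layer):
    """Parallel conv branches concatenated along channels.

    Branches: 1x1 conv; 1x1 -> 3x3; 1x1 -> 3x3 -> 3x3; 3x3 avg pool -> 1x1.
    Each conv is followed by batch norm + ReLU.
    """

    def __init__(self, in_ch: int, widths: tuple[int, int, int, int],
                 rng: np.random.Generator) -> None:
        super().__init__()
        w1, w3, w5, wp = widths

        def conv_bn_relu(cin, cout, k):
            return [Conv2D(cin, cout, ksize=k, rng=rng), BatchNorm(cout), ReLU()]

        self.branches: list[list[Layer]] = [
            conv_bn_relu(in_ch, w1, 1),
            conv_bn_relu(in_ch, w3, 1) + conv_bn_relu(w3, w3, 3),
            conv_bn_relu(in_ch, w5, 1) + conv_bn_relu(w5, w5, 3) + conv_bn_relu(w5, w5, 3),
            [AvgPool3x3Same()] + conv_bn_relu(in_ch, wp, 1),
        ]
        self.out_ch = w1 + w3 + w5 + wp
        self._splits = np.cumsum([w1, w3, w5, wp])[:-1]
        for br in self.branches:
            for lay in br:
                self.params.extend(lay.params)
                self.grads.extend(lay.grads)

    def forward(self, x, train):
        outs = []
        for br in self.branches:
            h = x
            for lay in br:
                h = lay.forward(h, train)
            outs.append(h)
        return np.concatenate(outs, axis=-1)

    def backward(self, grad):
        parts = np.split(grad, self._splits, axis=-1)
        dx = None
        for br, g in zip(self.branches, parts):
            for lay in reversed(br):
                g = lay.backward(g)
            dx = g if dx is None else dx + g
        return dx

    def out_shape(self, in_shape):
        return (in_shape[0], in_shape[1], self.out_ch)
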