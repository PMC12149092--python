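"""Neural-network layers on the autodiff core.

All layers follow a ``(batch, time, channels)`` convention for sequence
input and ``(batch, features)`` for flat input.  Each layer exposes
``__call__(x, training)`` and ``parameters()``; initialization is seeded
through the ``rng`` passed at construction.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .autograd import Tensor, concatenate, stack

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "BatchNorm",
    "Flatten",
    "Conv1d",
    "AvgPool1d",
    "LSTM",
    "GRU",
    "Sequential",
]


class Layer:
    def parameters(self) -> list[Tensor]:
        return []

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return x @ self.w + self.b


class ReLU(Layer):
    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return x.relu()


class Sigmoid(Layer):
    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return x.sigmoid()


class Flatten(Layer):
    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if not training or self.rate == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * Tensor(mask)


class BatchNorm(Layer):
    """Batch normalization over the batch (and time, for sequences) axes.

    Uses batch statistics during training and exponential running averages
    at inference.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes, keepdims=True)
            centered = x - mean
            var = (centered**2).mean(axis=axes, keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean
                + (1 - self.momentum) * mean.data.reshape(-1)
            )
            self.running_var = (
                self.momentum * self.running_var
                + (1 - self.momentum) * var.data.reshape(-1)
            )
            norm = centered / (var + self.eps) ** 0.5
        else:
            norm = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return norm * self.gamma + self.beta


class Conv1d(Layer):
    """1-D convolution over (batch, time, channels) with 'same' padding."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
    ):
        fan_in = n_in * kernel_size
        self.w = _glorot(rng, (kernel_size, n_in, n_out), fan_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.kernel_size = kernel_size
        self.stride = stride

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        k, s = self.kernel_size, self.stride
        w, b = self.w, self.b
        pad_l = (k - 1) // 2
        pad_r = k - 1 - pad_l
        xd = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(xd, k, axis=1)[:, ::s]
        # windows: (B, T_out, C_in, K)
        out_data = np.einsum("btck,kco->bto", windows, w.data) + b.data

        def bw(g):
            if w.requires_grad:
                w._accum(np.einsum("btck,bto->kco", windows, g))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 1)))
            if x.requires_grad:
                gx = np.zeros_like(xd)
                t_out = g.shape[1]
                for kk in range(k):
                    np.add.at(
                        gx,
                        (slice(None), slice(kk, kk + t_out * s, s), slice(None)),
                        np.einsum("bto,co->btc", g, w.data[kk]),
                    )
                x._accum(gx[:, pad_l : xd.shape[1] - pad_r or None, :])

        return Tensor._from_op(out_data, (x, w, b), bw)


class AvgPool1d(Layer):
    """Average pooling over time with 'same' padding, stride 1."""

    def __init__(self, kernel_size: int = 3):
        self.kernel_size = kernel_size

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        k = self.kernel_size
        pad_l = (k - 1) // 2
        pad_r = k - 1 - pad_l
        xd = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(xd, k, axis=1)
        out_data = windows.mean(axis=-1)

        def bw(g):
            gx = np.zeros_like(xd)
            t_out = g.shape[1]
            for kk in range(k):
                gx[:, kk : kk + t_out, :] += g / k
            x._accum(gx[:, pad_l : xd.shape[1] - pad_r or None, :])

        return Tensor._from_op(out_data, (x,), bw)


class _Recurrent(Layer):
    def __init__(
        self,
        n_in: int,
        n_units: int,
        rng: np.random.Generator,
        return_sequences: bool,
        n_gates: int,
    ):
        self.n_units = n_units
        self.return_sequences = return_sequences
        self.wx = _glorot(rng, (n_in, n_gates * n_units), n_in, n_units)
        self.wh = _glorot(rng, (n_units, n_gates * n_units), n_units, n_units)
        self.b = Tensor(np.zeros(n_gates * n_units), requires_grad=True)

    def parameters(self):
        return [self.wx, self.wh, self.b]


class LSTM(_Recurrent):
    """Standard LSTM over (batch, time, features); gate order i, f, g, o."""

    def __init__(self, n_in, n_units, rng, return_sequences=True):
        super().__init__(n_in, n_units, rng, return_sequences, 4)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        b_sz, t_len, _ = x.shape
        h_dim = self.n_units
        h = Tensor(np.zeros((b_sz, h_dim)))
        c = Tensor(np.zeros((b_sz, h_dim)))
        outs = []
        for t in range(t_len):
            xt = x[:, t, :]
            z = xt @ self.wx + h @ self.wh + self.b
            i = z[:, 0 * h_dim : 1 * h_dim].sigmoid()
            f = z[:, 1 * h_dim : 2 * h_dim].sigmoid()
            g = z[:, 2 * h_dim : 3 * h_dim].tanh()
            o = z[:, 3 * h_dim : 4 * h_dim].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            if self.return_sequences:
                outs.append(h)
        return stack(outs, axis=1) if self.return_sequences else h


class GRU(_Recurrent):
    """Gated recurrent unit; gate order z (update), r (reset), n (candidate)."""

    def __init__(self, n_in, n_units, rng, return_sequences=True):
        super().__init__(n_in, n_units, rng, return_sequences, 3)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        b_sz, t_len, _ = x.shape
        h_dim = self.n_units
        h = Tensor(np.zeros((b_sz, h_dim)))
        outs = []
        for t in range(t_len):
            xt = x[:, t, :]
            zx = xt @ self.wx + self.b
            zh = h @ self.wh
            z = (zx[:, 0 * h_dim : 1 * h_dim] + zh[:, 0 * h_dim : 1 * h_dim]).sigmoid()
            r = (zx[:, 1 * h_dim : 2 * h_dim] + zh[:, 1 * h_dim : 2 * h_dim]).sigmoid()
            n = (zx[:, 2 * h_dim : 3 * h_dim] + r * zh[:, 2 * h_dim : 3 * h_dim]).tanh()
            h = (1.0 - z) * n + z * h
            if self.return_sequences:
                outs.append(h)
        return stack(outs, axis=1) if self.return_sequences else h


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        for layer in self.layers:
            x = layer(x, training)
        return x
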