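"""The four classifier architectures behind a single Network contract.

* MLP — six fully connected ReLU layers of 64 units, sigmoid output.
* LSTM — recurrent layers of 100 and 50 units returning sequences (batch
  normalization after the first, 20% dropout after the second), a final
  25-unit layer returning the last state, sigmoid output.
* InceptionTime — stacked inception modules, each with parallel
  convolutions of kernel sizes 1, 3 and 5 plus an average-pool + 1x1
  convolution branch, concatenated on the channel axis; the filter count
  per branch grows across modules (16, 32, 64); flatten + sigmoid dense.
* ChronoNet — convolutional blocks of three parallel convolutions with
  different kernel sizes concatenated on the channel axis (ReLU), feeding
  stacked GRU layers; sigmoid dense on the final state.

Flat input (batch, features) feeds the MLP; sequence input
(batch, steps, features-per-step) feeds the other three.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autograd import Tensor, concatenate
from .layers import (
    AvgPool1d,
    BatchNorm,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    GRU,
    LSTM,
    Layer,
    ReLU,
    Sequential,
    Sigmoid,
)

__all__ = ["Network", "build_mlp", "build_lstm", "build_inception_time",
           "build_chrononet"]


class Network:
    """A forward-callable stack of layers ending in a sigmoid unit."""

    def __init__(self, body: Layer, needs_sequence: bool):
        self.body = body
        self.needs_sequence = needs_sequence

    def parameters(self) -> list[Tensor]:
        return self.body.parameters()

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        """Probability of class 1, shape (batch,)."""
        out = self.body(x, training)
        return out.reshape(out.shape[0])


def build_mlp(n_features: int, rng: np.random.Generator,
              hidden: Sequence[int] = (64,) * 6) -> Network:
    layers: list[Layer] = []
    n_in = n_features
    for width in hidden:
        layers += [Dense(n_in, width, rng), ReLU()]
        n_in = width
    layers += [Dense(n_in, 1, rng), Sigmoid()]
    return Network(Sequential(*layers), needs_sequence=False)


def build_lstm(
    n_steps: int,
    n_features: int,
    rng: np.random.Generator,
    units: Sequence[int] = (100, 50, 25),
    dropout: float = 0.2,
) -> Network:
    u1, u2, u3 = units
    body = Sequential(
        LSTM(n_features, u1, rng, return_sequences=True),
        BatchNorm(u1),
        LSTM(u1, u2, rng, return_sequences=True),
        Dropout(dropout, rng),
        LSTM(u2, u3, rng, return_sequences=False),
        Dense(u3, 1, rng),
        Sigmoid(),
    )
    return Network(body, needs_sequence=True)


class _InceptionModule(Layer):
    """Parallel convolutions (kernels 1/3/5) + avg-pool->1x1 conv branch,
    concatenated on the channel axis, ReLU."""

    def __init__(self, n_in: int, n_filters: int, rng: np.random.Generator):
        self.convs = [Conv1d(n_in, n_filters, k, rng) for k in (1, 3, 5)]
        self.pool = AvgPool1d(3)
        self.pool_conv = Conv1d(n_in, n_filters, 1, rng)
        self.n_out = 4 * n_filters

    def parameters(self):
        ps = [p for c in self.convs for p in c.parameters()]
        return ps + self.pool_conv.parameters()

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        branches = [c(x, training) for c in self.convs]
        branches.append(self.pool_conv(self.pool(x, training), training))
        return concatenate(branches, axis=-1).relu()


def build_inception_time(
    n_steps: int,
    n_features: int,
    rng: np.random.Generator,
    filters: Sequence[int] = (16, 32, 64),
) -> Network:
    layers: list[Layer] = []
    n_in = n_features
    for nf in filters:
        mod = _InceptionModule(n_in, nf, rng)
        layers.append(mod)
        n_in = mod.n_out
    layers += [Flatten(), Dense(n_steps * n_in, 1, rng), Sigmoid()]
    return Network(Sequential(*layers), needs_sequence=True)


class _ChronoBlock(Layer):
    """Three parallel convolutions with different kernel sizes, ReLU,
    concatenated on the channel axis."""

    def __init__(self, n_in: int, n_filters: int, rng: np.random.Generator,
                 kernels: Sequence[int] = (2, 4, 8)):
        self.convs = [Conv1d(n_in, n_filters, k, rng) for k in kernels]
        self.n_out = len(kernels) * n_filters

    def parameters(self):
        return [p for c in self.convs for p in c.parameters()]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return concatenate([c(x, training) for c in self.convs], axis=-1).relu()


def build_chrononet(
    n_steps: int,
    n_features: int,
    rng: np.random.Generator,
    conv_filters: int = 16,
    n_conv_blocks: int = 2,
    gru_units: Sequence[int] = (32, 32),
) -> Network:
    layers: list[Layer] = []
    n_in = n_features
    for _ in range(n_conv_blocks):
        block = _ChronoBlock(n_in, conv_filters, rng)
        layers.append(block)
        n_in = block.n_out
    for i, u in enumerate(gru_units):
        last = i == len(gru_units) - 1
        layers.append(GRU(n_in, u, rng, return_sequences=not last))
        n_in = u
    layers += [Dense(n_in, 1, rng), Sigmoid()]
    return Network(Sequential(*layers), needs_sequence=True)
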