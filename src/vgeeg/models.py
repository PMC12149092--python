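"""Training/prediction contract over the four classifier architectures.

A :class:`ModelSpec` names the architecture and its training
hyper-parameters; :func:`build_model` instantiates the seeded network,
:func:`fit` minimizes binary cross-entropy with Adam, and
:func:`predict_proba` returns class-1 probabilities.

Sequence-model input shaping: a flat feature row is regrouped into one
step per (channel, band) pair, with that pair's features (8 visibility
features, 1 band power, or both) as the per-step channels.  This gives
recurrent and convolutional models a physically meaningful axis to scan.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import FeatureRow
from .nn import (
    Network,
    Tensor,
    build_chrononet,
    build_inception_time,
    build_lstm,
    build_mlp,
)

__all__ = ["TrainingParams", "ModelSpec", "FittedModel", "build_model", "fit",
           "predict_proba", "save_model", "load_model"]

ARCHITECTURES = ("mlp", "lstm", "inception_time", "chrononet")


@dataclass(frozen=True)
class TrainingParams:
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass(frozen=True)
class ModelSpec:
    architecture: str = "mlp"
    training: TrainingParams = field(default_factory=TrainingParams)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {ARCHITECTURES}"
            )


def sequence_layout(
    layout: Sequence[tuple[str, str, str]]
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Group a flat layout into (channel, band) steps.

    Returns the ordered list of groups and an integer index matrix of shape
    (n_steps, features_per_step) mapping into the flat vector.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for idx, (ch, band, _feat) in enumerate(layout):
        groups.setdefault((ch, band), []).append(idx)
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1:
        raise ValueError("layout groups have unequal feature counts")
    keys = list(groups)
    index = np.array([groups[k] for k in keys], dtype=int)
    return keys, index


def _design_matrix(rows: Sequence[FeatureRow], needs_sequence: bool) -> np.ndarray:
    x = np.stack([r.values for r in rows])
    if not needs_sequence:
        return x
    _, index = sequence_layout(rows[0].layout)
    return x[:, index]  # (batch, steps, features_per_step)


def build_model(spec: ModelSpec, layout: Sequence[tuple[str, str, str]]) -> Network:
    """Instantiate the seeded, untrained network for a feature layout."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.training.seed, 0]))
    arch = spec.architecture
    if arch == "mlp":
        return build_mlp(len(layout), rng)
    keys, index = sequence_layout(layout)
    n_steps, n_feat = index.shape
    if n_steps < 2:
        raise ValueError(
            f"sequence architecture {arch!r} needs >= 2 (channel, band) steps"
        )
    if arch == "lstm":
        return build_lstm(n_steps, n_feat, rng)
    if arch == "inception_time":
        return build_inception_time(n_steps, n_feat, rng)
    return build_chrononet(n_steps, n_feat, rng)


class _Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None


def _bce(prob: Tensor, y: np.ndarray) -> Tensor:
    eps = 1e-7
    yt = Tensor(y)
    return -(
        yt * (prob + eps).log() + (1.0 - yt) * (1.0 - prob + eps).log()
    ).mean()


@dataclass
class FittedModel:
    spec: ModelSpec
    network: Network
    layout: tuple[tuple[str, str, str], ...]
    training_history: list[float]

    def predict_proba(self, rows: Sequence[FeatureRow]) -> np.ndarray:
        return predict_proba(self, rows)

    def predict(self, rows: Sequence[FeatureRow]) -> np.ndarray:
        return (self.predict_proba(rows) >= 0.5).astype(int)


def fit(spec: ModelSpec, train_rows: Sequence[FeatureRow]) -> FittedModel:
    """Train the spec's architecture on the rows (binary cross-entropy,
    Adam, mini-batches).  Deterministic given the spec seed."""
    if len(train_rows) < 2:
        raise ValueError("need at least 2 training rows")
    labels = np.array([r.label for r in train_rows], dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    layout = train_rows[0].layout
    net = build_model(spec, layout)
    x = _design_matrix(train_rows, net.needs_sequence)
    tp = spec.training
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([tp.seed, 1]))
    opt = _Adam(net.parameters(), tp.learning_rate)
    history: list[float] = []
    n = len(train_rows)
    for _epoch in range(tp.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, tp.batch_size):
            idx = order[start : start + tp.batch_size]
            xb = Tensor(x[idx])
            prob = net.forward(xb, training=True)
            loss = _bce(prob, labels[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
        history.append(sum(losses) / n)
    return FittedModel(spec, net, tuple(layout), history)


def predict_proba(fitted: FittedModel, rows: Sequence[FeatureRow]) -> np.ndarray:
    """Class-1 probability per row, in [0, 1]."""
    if not rows:
        return np.zeros(0)
    if tuple(rows[0].layout) != fitted.layout:
        raise ValueError("feature layout does not match the fitted model")
    x = _design_matrix(rows, fitted.network.needs_sequence)
    out = fitted.network.forward(Tensor(x), training=False)
    return np.clip(out.data, 0.0, 1.0)


# ---------------------------------------------------------------------------
# persistence


def save_model(fitted: FittedModel, path: str | Path) -> Path:
    """Serialize spec + parameters + running stats to one .npz file."""
    path = Path(path)
    arrays = {f"param_{i}": p.data for i, p in enumerate(fitted.network.parameters())}
    meta = {
        "spec": {
            "architecture": fitted.spec.architecture,
            "training": asdict(fitted.spec.training),
        },
        "layout": [list(e) for e in fitted.layout],
        "training_history": fitted.training_history,
    }
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    path.write_bytes(buf.getvalue())
    return path


def load_model(path: str | Path) -> FittedModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec = ModelSpec(
            architecture=meta["spec"]["architecture"],
            training=TrainingParams(**meta["spec"]["training"]),
        )
        layout = tuple(tuple(e) for e in meta["layout"])
        net = build_model(spec, layout)
        for i, p in enumerate(net.parameters()):
            p.data = np.array(data[f"param_{i}"])
    return FittedModel(spec, net, layout, list(meta["training_history"]))
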