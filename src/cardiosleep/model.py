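"""Multi-task network: shared recurrent trunk with event and sleep heads.

The input is a 5-min window of two 4 Hz channels (RR tachogram and
respiratory effort), shape (batch, 1200, 2).  A shared trunk of two
bidirectional-GRU blocks downsamples time 1200 -> 600 -> 300 so its output
is at 1 Hz.  The event head keeps the 1 Hz resolution and emits one
probability per second (300 values).  The sleep head applies a
time-axis convolutional stack that pools 300 -> 60 -> 20 -> 10, one
probability per 30-s epoch.  Both heads end in sigmoid units; training
uses the pre-sigmoid logits with a binary cross-entropy loss.

Layer order inside a shared block is GRU, GRU, batch norm, max-pool,
ReLU, dropout; head feature blocks drop the pooling step.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    BatchNorm,
    BiGRU,
    ConvTime,
    Dense,
    Dropout,
    ExpandChannel,
    FlattenFeatures,
    MaxPoolTime,
    ReLU,
    Sequential,
)
from .types import SEGMENT_EVENT_LEN, SEGMENT_SLEEP_LEN, SEGMENT_X_LEN

__all__ = [
    "ModelHyper",
    "MultiTaskModel",
    "SingleTaskModel",
    "build_model",
    "build_single_task_model",
    "trace_shapes",
]


@dataclass(frozen=True)
class ModelHyper:
    """Architecture hyper-parameters.

    The pooling structure is constrained by the printed label shapes: the
    shared pools must multiply to 4 (1200 -> 300, i.e. 4 Hz -> 1 Hz) and
    the sleep-head pools to 30 (300 s -> ten 30-s epochs).  Everything
    else (unit counts, kernel lengths, dropout) is free capacity.
    """

    gru_shared: tuple[int, int] = (64, 64)
    gru_event: int = 64
    gru_sleep: int = 64
    conv_filters: tuple[int, int, int] = (32, 32, 32)
    conv_kernels: tuple[int, int, int] = (5, 5, 5)
    pool_shared: tuple[int, int] = (2, 2)
    pool_sleep: tuple[int, int, int] = (5, 3, 2)
    dense_hidden: int = 64
    dropout: float = 0.2
    l2_strength: float = 1e-4

    def __post_init__(self) -> None:
        if math.prod(self.pool_shared) != 4:
            raise ValueError(
                f"shared pool factors {self.pool_shared} must multiply to 4 "
                "(1200 input samples -> 300 event labels)"
            )
        if math.prod(self.pool_sleep) != 30:
            raise ValueError(
                f"sleep-head pool factors {self.pool_sleep} must multiply to 30 "
                "(300 event-rate steps -> 10 sleep epochs)"
            )
        if any(u <= 0 for u in (*self.gru_shared, self.gru_event, self.gru_sleep,
                                 *self.conv_filters, self.dense_hidden)):
            raise ValueError("unit counts must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be non-negative")
        if any(k % 2 == 0 for k in self.conv_kernels):
            raise ValueError("conv kernel lengths must be odd")

    @staticmethod
    def reduced() -> "ModelHyper":
        """Small-capacity configuration for desk-scale experiments."""
        return ModelHyper(
            gru_shared=(8, 8), gru_event=8, gru_sleep=8,
            conv_filters=(4, 4, 4), conv_kernels=(5, 5, 5),
            dense_hidden=16,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelHyper":
        d = dict(d)
        for key in ("gru_shared", "conv_filters", "conv_kernels",
                    "pool_shared", "pool_sleep"):
            if key in d:
                d[key] = tuple(d[key])
        return ModelHyper(**d)


def _shared_trunk(hyper: ModelHyper, rng, drop_rng, dtype) -> tuple[Sequential, int]:
    layers = []
    in_dim = 2
    for i, (units, pool) in enumerate(zip(hyper.gru_shared, hyper.pool_shared)):
        layers += [
            BiGRU(in_dim, units, rng, dtype, name=f"shared{i}.gru0"),
            BiGRU(2 * units, units, rng, dtype, name=f"shared{i}.gru1"),
            BatchNorm(2 * units, dtype, name=f"shared{i}.bn"),
            MaxPoolTime(pool),
            ReLU(),
            Dropout(hyper.dropout, drop_rng),
        ]
        in_dim = 2 * units
    return Sequential(*layers), in_dim


def _event_head(hyper: ModelHyper, in_dim, rng, drop_rng, dtype) -> Sequential:
    u = hyper.gru_event
    return Sequential(
        BiGRU(in_dim, u, rng, dtype, name="event.gru0"),
        BiGRU(2 * u, u, rng, dtype, name="event.gru1"),
        BatchNorm(2 * u, dtype, name="event.bn"),
        ReLU(),
        Dropout(hyper.dropout, drop_rng),
        Dense(2 * u, hyper.dense_hidden, rng, dtype, name="event.fc0"),
        ReLU(),
        Dense(hyper.dense_hidden, 1, rng, dtype, name="event.out"),
    )


def _sleep_head(hyper: ModelHyper, in_dim, rng, drop_rng, dtype) -> Sequential:
    u = hyper.gru_sleep
    layers = [
        BiGRU(in_dim, u, rng, dtype, name="sleep.gru0"),
        BiGRU(2 * u, u, rng, dtype, name="sleep.gru1"),
        BatchNorm(2 * u, dtype, name="sleep.bn"),
        ReLU(),
        Dropout(hyper.dropout, drop_rng),
        ExpandChannel(),
    ]
    ch = 1
    for i, (f, k, pool) in enumerate(
        zip(hyper.conv_filters, hyper.conv_kernels, hyper.pool_sleep)
    ):
        layers += [
            ConvTime(ch, f, k, rng, dtype, name=f"sleep.conv{i}"),
            ReLU(),
            BatchNorm(f, dtype, name=f"sleep.convbn{i}"),
            MaxPoolTime(pool),
            Dropout(hyper.dropout, drop_rng),
        ]
        ch = f
    layers += [
        FlattenFeatures(),
        Dense(2 * u * ch, hyper.dense_hidden, rng, dtype, name="sleep.fc0"),
        ReLU(),
        Dense(hyper.dense_hidden, 1, rng, dtype, name="sleep.out"),
    ]
    return Sequential(*layers)


class _BaseModel:
    hyper: ModelHyper
    trunk: Sequential

    def params(self):
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def l2_penalty(self) -> float:
        lam = self.hyper.l2_strength
        if lam == 0:
            return 0.0
        return lam * sum(float((p.value.astype(np.float64) ** 2).sum())
                         for p in self.params() if p.is_kernel)

    def add_l2_gradients(self) -> None:
        lam = self.hyper.l2_strength
        if lam == 0:
            return
        for p in self.params():
            if p.is_kernel:
                p.grad += (2.0 * lam * p.value).astype(p.grad.dtype)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {p.name: p.value.copy() for p in self.params()}
        for lay in self._all_layers():
            if isinstance(lay, BatchNorm):
                out[f"{lay.gamma.name}.running_mean"] = lay.running_mean.copy()
                out[f"{lay.gamma.name}.running_var"] = lay.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for lay in self._all_layers():
            if isinstance(lay, BatchNorm):
                lay.running_mean[...] = state[f"{lay.gamma.name}.running_mean"]
                lay.running_var[...] = state[f"{lay.gamma.name}.running_var"]

    def _all_layers(self):
        raise NotImplementedError

    @staticmethod
    def _check_input(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[1] != SEGMENT_X_LEN or X.shape[2] != 2:
            raise ValueError(
                f"input must have shape (batch, {SEGMENT_X_LEN}, 2), got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains non-finite values")
        return X


class MultiTaskModel(_BaseModel):
    """Shared trunk with SDB-event and sleep-wake heads."""

    def __init__(self, hyper: ModelHyper, seed: int = 0, dtype=np.float32):
        self.hyper = hyper
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng([seed, 7919])
        self.trunk, trunk_out = _shared_trunk(hyper, rng, self.drop_rng, dtype)
        self.event_head = _event_head(hyper, trunk_out, rng, self.drop_rng, dtype)
        self.sleep_head = _sleep_head(hyper, trunk_out, rng, self.drop_rng, dtype)

    def _all_layers(self):
        return (
            self.trunk.layers + self.event_head.layers + self.sleep_head.layers
        )

    def params(self):
        return (
            self.trunk.params()
            + self.event_head.params()
            + self.sleep_head.params()
        )

    def forward_logits(self, X, train: bool):
        X = self._check_input(X)
        h = self.trunk.forward(X, train)
        z_event = self.event_head.forward(h, train)[..., 0]
        z_sleep = self.sleep_head.forward(h, train)[..., 0]
        return z_event, z_sleep

    def backward(self, d_event, d_sleep):
        dh = self.event_head.backward(
            np.asarray(d_event, self.dtype)[..., None]
        )
        dh = dh + self.sleep_head.backward(
            np.asarray(d_sleep, self.dtype)[..., None]
        )
        return self.trunk.backward(dh)

    def forward(self, X, train: bool = False):
        """Probability tracks: (batch, 300) event, (batch, 10) sleep."""
        z_event, z_sleep = self.forward_logits(X, train)
        return _sigmoid(z_event), _sigmoid(z_sleep)

    def predict(self, X, batch_size: int = 128):
        """Evaluation-mode prediction in mini-batches."""
        ps_event, ps_sleep = [], []
        for i in range(0, len(X), batch_size):
            pe, psl = self.forward(X[i : i + batch_size], train=False)
            ps_event.append(pe)
            ps_sleep.append(psl)
        return (
            np.concatenate(ps_event) if ps_event else np.zeros((0, SEGMENT_EVENT_LEN)),
            np.concatenate(ps_sleep) if ps_sleep else np.zeros((0, SEGMENT_SLEEP_LEN)),
        )


class SingleTaskModel(_BaseModel):
    """Event-detection-only comparison model: identical trunk + event head."""

    def __init__(self, hyper: ModelHyper, seed: int = 0, dtype=np.float32):
        self.hyper = hyper
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng([seed, 7919])
        self.trunk, trunk_out = _shared_trunk(hyper, rng, self.drop_rng, dtype)
        self.event_head = _event_head(hyper, trunk_out, rng, self.drop_rng, dtype)

    def _all_layers(self):
        return self.trunk.layers + self.event_head.layers

    def params(self):
        return self.trunk.params() + self.event_head.params()

    def forward_logits(self, X, train: bool):
        X = self._check_input(X)
        h = self.trunk.forward(X, train)
        return self.event_head.forward(h, train)[..., 0]

    def backward(self, d_event):
        dh = self.event_head.backward(np.asarray(d_event, self.dtype)[..., None])
        return self.trunk.backward(dh)

    def forward(self, X, train: bool = False):
        return _sigmoid(self.forward_logits(X, train))

    def predict(self, X, batch_size: int = 128):
        out = [self.forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
        return np.concatenate(out) if out else np.zeros((0, SEGMENT_EVENT_LEN))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, np.float64)))


def build_model(hyper: ModelHyper | None = None, seed: int = 0,
                dtype=np.float32) -> MultiTaskModel:
    return MultiTaskModel(hyper or ModelHyper(), seed=seed, dtype=dtype)


def build_single_task_model(hyper: ModelHyper | None = None, seed: int = 0,
                            dtype=np.float32) -> SingleTaskModel:
    return SingleTaskModel(hyper or ModelHyper(), seed=seed, dtype=dtype)


def trace_shapes(model: _BaseModel, batch: int = 2) -> list[tuple[str, tuple]]:
    """Run a dummy forward and record the output shape after every layer."""
    X = np.zeros((batch, SEGMENT_X_LEN, 2), np.float32)
    trace: list[tuple[str, tuple]] = [("input", X.shape)]
    h = X
    for lay in model.trunk.layers:
        h = lay.forward(h, train=False)
        trace.append((f"trunk.{type(lay).__name__}", h.shape))
    heads = [("event", model.event_head)]
    if isinstance(model, MultiTaskModel):
        heads.append(("sleep", model.sleep_head))
    for name, head in heads:
        y = h
        for lay in head.layers:
            y = lay.forward(y, train=False)
            trace.append((f"{name}.{type(lay).__name__}", y.shape))
    return trace
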