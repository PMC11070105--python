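"""Layer primitives with explicit forward/backward passes.

The network is a static DAG (shared trunk feeding two heads), so layers
keep their own caches from the last forward call and return input
gradients from ``backward``.  Parameters are held in :class:`Param`
objects; kernels (matrix weights) are distinguished from biases and
normalization coefficients so that L2 regularization and weight decay can
be applied to kernels only.
"""

from __future__ import annotations

import numpy as np

from .gru_kernels import gru_backward, gru_forward

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "BiGRU",
    "Dense",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "BatchNorm",
    "MaxPoolTime",
    "ExpandChannel",
    "FlattenFeatures",
    "ConvTime",
    "xavier_uniform",
]


def xavier_uniform(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    if len(shape) == 3:  # conv kernel (kt, C, O): receptive field kt*C
        fan_in = shape[0] * shape[1]
        fan_out = shape[0] * shape[2]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Param:
    __slots__ = ("name", "value", "grad", "is_kernel")

    def __init__(self, name: str, value: np.ndarray, is_kernel: bool):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.is_kernel = is_kernel

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class BiGRU(Layer):
    """Bidirectional GRU over (B, T, C) input, output (B, T, 2H)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "bigru"):
        self.in_dim = in_dim
        self.hidden = hidden
        self.dtype = np.dtype(dtype)
        self.p: dict[str, Param] = {}
        for d in ("fw", "bw"):
            self.p[f"Wx_{d}"] = Param(
                f"{name}.Wx_{d}", xavier_uniform(rng, (in_dim, 3 * hidden), dtype), True
            )
            self.p[f"Wh_{d}"] = Param(
                f"{name}.Wh_{d}", xavier_uniform(rng, (hidden, 3 * hidden), dtype), True
            )
            self.p[f"bx_{d}"] = Param(
                f"{name}.bx_{d}", np.zeros(3 * hidden, dtype), False
            )
            self.p[f"bh_{d}"] = Param(
                f"{name}.bh_{d}", np.zeros(3 * hidden, dtype), False
            )
        self._cache = None

    def params(self):
        return list(self.p.values())

    def _run_dir(self, xt: np.ndarray, d: str):
        """xt: (T, B, C) already ordered for this direction."""
        T, B, _ = xt.shape
        H = self.hidden
        Wx, Wh = self.p[f"Wx_{d}"].value, self.p[f"Wh_{d}"].value
        bx, bh = self.p[f"bx_{d}"].value, self.p[f"bh_{d}"].value
        xp = np.ascontiguousarray(
            xt.reshape(T * B, -1) @ Wx + bx
        ).reshape(T, B, 3 * H)
        out_h = np.empty((T, B, H), self.dtype)
        r = np.empty_like(out_h)
        z = np.empty_like(out_h)
        n = np.empty_like(out_h)
        hpn = np.empty_like(out_h)
        gru_forward(xp, Wh, bh, out_h, r, z, n, hpn)
        return out_h, (xp, out_h, r, z, n, hpn)

    def forward(self, x, train):
        x = np.ascontiguousarray(x, self.dtype)
        xt = np.ascontiguousarray(x.transpose(1, 0, 2))  # (T, B, C)
        xt_rev = np.ascontiguousarray(xt[::-1])
        h_fw, cache_fw = self._run_dir(xt, "fw")
        h_bw_rev, cache_bw = self._run_dir(xt_rev, "bw")
        h_bw = h_bw_rev[::-1]
        y = np.concatenate([h_fw, h_bw], axis=2)  # (T, B, 2H)
        self._cache = (xt, xt_rev, cache_fw, cache_bw)
        return np.ascontiguousarray(y.transpose(1, 0, 2))

    def _back_dir(self, dh_out: np.ndarray, xt: np.ndarray, cache, d: str):
        T, B, H = dh_out.shape
        xp, out_h, r, z, n, hpn = cache
        Wx, Wh = self.p[f"Wx_{d}"].value, self.p[f"Wh_{d}"].value
        dxp = np.zeros_like(xp)
        dWh = np.zeros_like(Wh)
        dbh = np.zeros(3 * H, self.dtype)
        gru_backward(np.ascontiguousarray(dh_out), out_h, r, z, n, hpn,
                     Wh, dxp, dWh, dbh)
        self.p[f"Wh_{d}"].grad += dWh
        self.p[f"bh_{d}"].grad += dbh
        xf = xt.reshape(T * B, -1)
        df = dxp.reshape(T * B, -1)
        self.p[f"Wx_{d}"].grad += xf.T @ df
        self.p[f"bx_{d}"].grad += df.sum(axis=0)
        return (df @ Wx.T).reshape(T, B, -1)

    def backward(self, dy):
        xt, xt_rev, cache_fw, cache_bw = self._cache
        H = self.hidden
        dyt = np.ascontiguousarray(dy.transpose(1, 0, 2), self.dtype)
        dx = self._back_dir(dyt[:, :, :H], xt, cache_fw, "fw")
        dx_rev = self._back_dir(
            np.ascontiguousarray(dyt[::-1, :, H:]), xt_rev, cache_bw, "bw"
        )
        dx = dx + dx_rev[::-1]
        return np.ascontiguousarray(dx.transpose(1, 0, 2))


class Dense(Layer):
    """Affine map on the trailing axis (time-distributed when rank > 2)."""

    def __init__(self, in_dim, out_dim, rng, dtype=np.float32, name="dense"):
        self.W = Param(f"{name}.W", xavier_uniform(rng, (in_dim, out_dim), dtype), True)
        self.b = Param(f"{name}.b", np.zeros(out_dim, dtype), False)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        x = self._x
        xf = x.reshape(-1, x.shape[-1])
        df = dy.reshape(-1, dy.shape[-1])
        self.W.grad += xf.T @ df
        self.b.grad += df.sum(axis=0)
        return (df @ self.W.value.T).reshape(x.shape)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class BatchNorm(Layer):
    """Normalize over all axes but the last (per-channel statistics)."""

    def __init__(self, dim: int, dtype=np.float32, momentum: float = 0.8,
                 eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(dim, dtype), False)
        self.beta = Param(f"{name}.beta", np.zeros(dim, dtype), False)
        self.running_mean = np.zeros(dim, dtype)
        self.running_var = np.ones(dim, dtype)
        self.momentum = momentum
        self.eps = eps
        self._cumulative_count: int | None = None

    def begin_cumulative_stats(self) -> None:
        """Switch to momentum-free averaging (precise-BN recalibration)."""
        self._cumulative_count = 0
        self.running_mean[...] = 0.0
        self.running_var[...] = 0.0

    def end_cumulative_stats(self) -> None:
        self._cumulative_count = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            xf = x.reshape(-1, x.shape[-1])
            n = xf.shape[0]
            mean = xf.mean(axis=0)
            # single extra pass: E[x^2] - E[x]^2 (float64 accumulator)
            sq = np.einsum("nc,nc->c", xf, xf, dtype=np.float64) / n
            var = np.maximum(sq - mean.astype(np.float64) ** 2, 0.0).astype(
                x.dtype
            )
            if self._cumulative_count is not None:
                k = self._cumulative_count
                self.running_mean = (
                    (k * self.running_mean + mean) / (k + 1)
                ).astype(self.running_mean.dtype)
                self.running_var = (
                    (k * self.running_var + var) / (k + 1)
                ).astype(self.running_var.dtype)
                self._cumulative_count = k + 1
            else:
                m = self.momentum
                self.running_mean = (
                    m * self.running_mean + (1 - m) * mean
                ).astype(self.running_mean.dtype)
                self.running_var = (
                    m * self.running_var + (1 - m) * var
                ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd, axes, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, invstd, axes, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        if not train:
            return dxhat * invstd
        n = xhat.size // xhat.shape[-1]
        return (
            invstd
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=axes)
                - xhat * (dxhat * xhat).sum(axis=axes)
            )
        )


class MaxPoolTime(Layer):
    """Non-overlapping max pooling along axis 1 (time)."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train):
        B, T = x.shape[:2]
        if T % self.k:
            raise ValueError(f"time length {T} not divisible by pool {self.k}")
        rest = x.shape[2:]
        xr = x.reshape(B, T // self.k, self.k, *rest)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(
            xr, np.expand_dims(self._argmax, 2), axis=2
        ).squeeze(axis=2)

    def backward(self, dy):
        B, T = self._in_shape[:2]
        rest = self._in_shape[2:]
        dxr = np.zeros((B, T // self.k, self.k, *rest), dy.dtype)
        np.put_along_axis(
            dxr, np.expand_dims(self._argmax, 2), np.expand_dims(dy, 2), axis=2
        )
        return dxr.reshape(self._in_shape)


class ExpandChannel(Layer):
    """(B, T, F) -> (B, T, F, 1): singleton channel for the conv stack."""

    def forward(self, x, train):
        return x[..., None]

    def backward(self, dy):
        return dy[..., 0]


class FlattenFeatures(Layer):
    """(B, T, F, C) -> (B, T, F*C): back to per-step feature vectors."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class ConvTime(Layer):
    """Convolution along the time axis of (B, T, F, C), 'same' padding.

    The kernel (kt, C, O) is shared across the feature axis F, i.e. a 2-D
    convolution with a (kt, 1) receptive field over the (time, feature)
    plane of each channel.
    """

    def __init__(self, in_ch, out_ch, kt, rng, dtype=np.float32, name="conv"):
        if kt % 2 == 0:
            raise ValueError("time kernel length must be odd for 'same' padding")
        self.kt = kt
        self.W = Param(f"{name}.W", xavier_uniform(rng, (kt, in_ch, out_ch), dtype), True)
        self.b = Param(f"{name}.b", np.zeros(out_ch, dtype), False)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        pad = (self.kt - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0), (0, 0)))
        self._xp = xp
        T = x.shape[1]
        y = np.zeros(x.shape[:3] + (self.W.value.shape[2],), x.dtype)
        for k in range(self.kt):
            y += xp[:, k : k + T] @ self.W.value[k]
        return y + self.b.value

    def backward(self, dy):
        xp = self._xp
        T = dy.shape[1]
        dxp = np.zeros_like(xp)
        for k in range(self.kt):
            xs = xp[:, k : k + T]
            self.W.grad[k] += np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, k : k + T] += dy @ self.W.value[k].T
        self.b.grad += dy.sum(axis=(0, 1, 2))
        pad = (self.kt - 1) // 2
        return dxp[:, pad : pad + T]
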