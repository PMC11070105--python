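"""Numerical gradient checks for every layer primitive and the full model.

Each check perturbs randomly chosen parameters (and inputs) of a
float64 network and compares the analytic backward pass against central
finite differences.  Parameters are randomized away from zero first so
no pre-activation sits exactly on a ReLU kink, where the subgradient
convention and the finite difference legitimately disagree.
"""

import numpy as np
import pytest

from cardiosleep.nn import (
    Adam,
    BatchNorm,
    BiGRU,
    ConvTime,
    Dense,
    Dropout,
    MaxPoolTime,
    ReLU,
    Sequential,
    bce_with_logits,
)
from cardiosleep.model import ModelHyper, MultiTaskModel


def _randomize(params, rng):
    for p in params:
        p.value += rng.normal(0.0, 0.05, size=p.value.shape)


def _check_grads(net, x, y_fn, rng, n_checks=4, tol=2e-4):
    """y_fn maps network output -> (scalar loss, dloss/dout)."""

    def loss():
        out = net.forward(x, True)
        return y_fn(out)

    L, dout = loss()
    for p in net.params():
        p.zero_grad()
    net.backward(dout)
    for p in net.params():
        flat = p.value.ravel()
        g = p.grad.ravel()
        for _ in range(n_checks):
            i = int(rng.integers(flat.size))
            eps = 1e-6
            old = flat[i]
            flat[i] = old + eps
            L1, _ = loss()
            flat[i] = old - eps
            L2, _ = loss()
            flat[i] = old
            num = (L1 - L2) / (2 * eps)
            assert abs(num - g[i]) <= tol * max(1.0, abs(num)), (
                f"{p.name}[{i}]: numeric {num:.6g} vs analytic {g[i]:.6g}"
            )


def _sq_loss(out):
    return 0.5 * float((out**2).sum()), out


@pytest.mark.parametrize(
    "build",
    [
        lambda rng: Sequential(Dense(4, 6, rng, np.float64), ReLU(),
                               Dense(6, 2, rng, np.float64)),
        lambda rng: Sequential(BiGRU(3, 4, rng, np.float64)),
        lambda rng: Sequential(BatchNorm(3, np.float64)),
        lambda rng: Sequential(MaxPoolTime(2), Dense(3, 2, rng, np.float64)),
    ],
    ids=["dense-relu", "bigru", "batchnorm", "maxpool-dense"],
)
def test_layer_gradients_match_finite_differences(build, rng):
    net = build(rng)
    _randomize(net.params(), rng)
    x = rng.normal(size=(3, 8, net.layers[0].in_dim if isinstance(net.layers[0], BiGRU) else 3))
    if isinstance(net.layers[0], Dense):
        x = rng.normal(size=(3, 8, 4))
    _check_grads(net, x, _sq_loss, rng)


def test_conv_time_gradients(rng):
    net = Sequential(ConvTime(2, 3, 5, rng, np.float64))
    _randomize(net.params(), rng)
    x = rng.normal(size=(2, 6, 4, 2))
    _check_grads(net, x, _sq_loss, rng)


def test_full_multitask_model_gradients(rng):
    hyper = ModelHyper(
        gru_shared=(3, 3), gru_event=3, gru_sleep=3, conv_filters=(2, 2, 2),
        dense_hidden=4, dropout=0.0, l2_strength=0.0,
    )
    m = MultiTaskModel(hyper, seed=1, dtype=np.float64)
    _randomize(m.params(), rng)
    X = rng.normal(size=(2, 1200, 2))
    ye = (rng.random((2, 300)) < 0.2).astype(float)
    ys = (rng.random((2, 10)) < 0.7).astype(float)

    def loss():
        ze, zs = m.forward_logits(X, train=True)
        le, dze = bce_with_logits(ze, ye)
        ls, dzs = bce_with_logits(zs, ys)
        return le + ls, (dze, dzs)

    L, (dze, dzs) = loss()
    for p in m.params():
        p.zero_grad()
    m.backward(dze, dzs)
    prng = np.random.default_rng(7)
    for p in m.params():
        flat = p.value.ravel()
        g = p.grad.ravel()
        i = int(prng.integers(flat.size))
        eps = 1e-6
        old = flat[i]
        flat[i] = old + eps
        L1, _ = loss()
        flat[i] = old - eps
        L2, _ = loss()
        flat[i] = old
        num = (L1 - L2) / (2 * eps)
        assert abs(num - g[i]) <= 2e-4 * max(1.0, abs(num)), p.name


def test_bce_with_logits_matches_direct_formula(rng):
    z = rng.normal(scale=3.0, size=200)
    y = (rng.random(200) < 0.3).astype(float)
    w = 1.0 + 9.0 * y
    loss, dz = bce_with_logits(z, y, w)
    p = 1.0 / (1.0 + np.exp(-z))
    direct = -(y * np.log(p) + (1 - y) * np.log(1 - p)) * w
    assert np.isclose(loss, direct.mean(), rtol=1e-10)
    assert np.allclose(dz, w * (p - y) / z.size, rtol=1e-10)


def test_dropout_scales_and_disables(rng):
    lay = Dropout(0.5, rng)
    x = np.ones((200, 50))
    y = lay.forward(x, train=True)
    assert set(np.unique(y)) <= {0.0, 2.0}  # inverted dropout
    assert abs(y.mean() - 1.0) < 0.05
    assert np.array_equal(lay.forward(x, train=False), x)


def test_adam_decreases_simple_quadratic(rng):
    from cardiosleep.nn import Param

    p = Param("w", rng.normal(size=5), True)
    opt = Adam([p], lr=0.05, weight_decay=0.0)
    for _ in range(200):
        opt.zero_grad()
        p.grad[...] = p.value  # grad of 0.5*||w||^2
        opt.step()
    assert np.abs(p.value).max() < 1e-2


def test_batchnorm_cumulative_stats_match_population(rng):
    bn = BatchNorm(4, np.float64)
    bn.begin_cumulative_stats()
    batches = [rng.normal(loc=2.0, scale=3.0, size=(64, 4)) for _ in range(10)]
    for b in batches:
        bn.forward(b, train=True)
    bn.end_cumulative_stats()
    allx = np.concatenate(batches)
    assert np.allclose(bn.running_mean, allx.mean(0), atol=0.05)
    assert np.allclose(bn.running_var, allx.var(0), rtol=0.05)
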