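"""Numba kernels for GRU forward and backward-through-time passes.

Layout is time-major: ``xp`` holds the precomputed input projections
``x_t @ Wx + bx`` with shape (T, B, 3H), gate order (r, z, n).  The update
follows the standard convention with a separate recurrent bias:

    r_t = sigmoid(xp_r + h W_hr + bh_r)
    z_t = sigmoid(xp_z + h W_hz + bh_z)
    n_t = tanh(xp_n + r_t * (h W_hn + bh_n))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

The nonlinearities use a clamped Pade approximation of tanh (max error
~4e-5, well below float32 training noise) so the inner loops vectorize;
the backward pass uses the matching algebraic derivative identities on
the stored gate values.
"""

import numpy as np
from numba import njit


@njit(fastmath=True, inline="always")
def _tanh(x):
    x = min(max(x, -4.97), 4.97)
    x2 = x * x
    return (
        x
        * (135135.0 + x2 * (17325.0 + x2 * (378.0 + x2)))
        / (135135.0 + x2 * (62370.0 + x2 * (3150.0 + x2 * 28.0)))
    )


@njit(fastmath=True, inline="always")
def _sigmoid(x):
    return 0.5 * (1.0 + _tanh(0.5 * x))


@njit(cache=True, fastmath=True)
def gru_forward(xp, Wh, bh, out_h, r, z, n, hpn):
    """Run the recurrence; fills out_h and the gate caches in place."""
    T, B, H3 = xp.shape
    H = H3 // 3
    h = np.zeros((B, H), dtype=Wh.dtype)
    for t in range(T):
        hp = np.dot(h, Wh)  # (B, 3H)
        for b in range(B):
            for j in range(H):
                rv = _sigmoid(xp[t, b, j] + hp[b, j] + bh[j])
                zv = _sigmoid(xp[t, b, H + j] + hp[b, H + j] + bh[H + j])
                hn = hp[b, 2 * H + j] + bh[2 * H + j]
                nv = _tanh(xp[t, b, 2 * H + j] + rv * hn)
                r[t, b, j] = rv
                z[t, b, j] = zv
                n[t, b, j] = nv
                hpn[t, b, j] = hn
                out_h[t, b, j] = (1.0 - zv) * nv + zv * h[b, j]
        h = out_h[t]


@njit(cache=True, fastmath=True)
def gru_backward(dh_out, out_h, r, z, n, hpn, Wh, dxp, dWh, dbh):
    """Backprop through time; fills dxp, dWh, dbh in place (must be zeroed)."""
    T, B, H = dh_out.shape
    dh = np.zeros((B, H), dtype=Wh.dtype)
    d_hp = np.zeros((B, 3 * H), dtype=Wh.dtype)
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for j in range(H):
                dhv = dh[b, j] + dh_out[t, b, j]
                hprev = out_h[t - 1, b, j] if t > 0 else 0.0
                zv = z[t, b, j]
                nv = n[t, b, j]
                rv = r[t, b, j]
                hn = hpn[t, b, j]
                dz = dhv * (hprev - nv)
                dn = dhv * (1.0 - zv)
                dh[b, j] = dhv * zv  # partial dh_{t-1}; recurrent term added below
                dan = dn * (1.0 - nv * nv)
                dar = dan * hn * rv * (1.0 - rv)
                daz = dz * zv * (1.0 - zv)
                dxp[t, b, j] = dar
                dxp[t, b, H + j] = daz
                dxp[t, b, 2 * H + j] = dan
                d_hp[b, j] = dar
                d_hp[b, H + j] = daz
                d_hp[b, 2 * H + j] = dan * rv
        for k in range(3 * H):
            s = 0.0
            for b in range(B):
                s += d_hp[b, k]
            dbh[k] += s
        if t > 0:
            for j in range(H):
                for k in range(3 * H):
                    s = 0.0
                    for b in range(B):
                        s += out_h[t - 1, b, j] * d_hp[b, k]
                    dWh[j, k] += s
        for b in range(B):
            for j in range(H):
                s = 0.0
                for k in range(3 * H):
                    s += d_hp[b, k] * Wh[j, k]
                dh[b, j] += s
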