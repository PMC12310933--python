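"""Fused single-pass kernels for the hottest tensor ops.

Layer normalisation and row softmax are memory-bound when expressed as NumPy
temporaries; these numba kernels do each in one or two passes.  The pure-NumPy
implementations in ``_tensor`` remain the reference path (and the fallback if
numba is unavailable); the test suite checks the two agree.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAS_NUMBA = True
except ImportError:          # pragma: no cover - numba is a hard dep in practice
    HAS_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


@njit(cache=True, fastmath=True)
def ln_forward(x, gamma, beta, eps):
    """Row-wise layer norm on (R, d); returns (out, mean, inv_std)."""
    R, d = x.shape
    out = np.empty_like(x)
    mu = np.empty(R, np.float32)
    inv = np.empty(R, np.float32)
    for i in range(R):
        s = np.float32(0.0)
        for j in range(d):
            s += x[i, j]
        m = s / d
        v = np.float32(0.0)
        for j in range(d):
            t = x[i, j] - m
            v += t * t
        iv = np.float32(1.0) / np.sqrt(v / d + eps)
        mu[i] = m
        inv[i] = iv
        for j in range(d):
            out[i, j] = (x[i, j] - m) * iv * gamma[j] + beta[j]
    return out, mu, inv


@njit(cache=True, fastmath=True)
def ln_backward(g, x, gamma, mu, inv):
    """Gradients of ln_forward: returns (gx, ggamma, gbeta)."""
    R, d = x.shape
    gx = np.empty_like(x)
    ggamma = np.zeros(d, np.float32)
    gbeta = np.zeros(d, np.float32)
    for i in range(R):
        mgh = np.float32(0.0)
        mxh = np.float32(0.0)
        for j in range(d):
            xh = (x[i, j] - mu[i]) * inv[i]
            gh = g[i, j] * gamma[j]
            mgh += gh
            mxh += gh * xh
            ggamma[j] += g[i, j] * xh
            gbeta[j] += g[i, j]
        mgh /= d
        mxh /= d
        for j in range(d):
            xh = (x[i, j] - mu[i]) * inv[i]
            gx[i, j] = inv[i] * (g[i, j] * gamma[j] - mgh - xh * mxh)
    return gx, ggamma, gbeta


@njit(cache=True, fastmath=True)
def softmax_forward(x):
    """Row softmax on (R, L) without masking."""
    R, L = x.shape
    p = np.empty_like(x)
    for i in range(R):
        m = x[i, 0]
        for j in range(1, L):
            if x[i, j] > m:
                m = x[i, j]
        s = np.float32(0.0)
        for j in range(L):
            e = np.exp(x[i, j] - m)
            p[i, j] = e
            s += e
        for j in range(L):
            p[i, j] /= s
    return p


@njit(cache=True, fastmath=True)
def softmax_backward(g, p):
    """gx = p * (g - sum(g * p)) per row."""
    R, L = p.shape
    gx = np.empty_like(p)
    for i in range(R):
        dot = np.float32(0.0)
        for j in range(L):
            dot += g[i, j] * p[i, j]
        for j in range(L):
            gx[i, j] = p[i, j] * (g[i, j] - dot)
    return gx
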