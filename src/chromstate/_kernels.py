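"""Numba kernels for the sequential HMM recursions and Markov sampling.

These are the only loops in the package that run once per genomic bin, so
they are jitted; everything else is vectorized numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def sample_markov_path(init_cdf, trans_cdf, uniforms):
    """Draw a state path from cumulative initial/transition distributions.

    ``init_cdf``: (K,) cumulative initial probabilities.
    ``trans_cdf``: (K, K) cumulative rows of the transition matrix.
    ``uniforms``: (L,) iid U(0,1) draws, one per bin.
    """
    L = uniforms.shape[0]
    K = init_cdf.shape[0]
    path = np.empty(L, np.int32)
    s = K - 1
    for k in range(K):
        if uniforms[0] < init_cdf[k]:
            s = k
            break
    path[0] = s
    for t in range(1, L):
        u = uniforms[t]
        nxt = K - 1
        for k in range(K):
            if u < trans_cdf[s, k]:
                nxt = k
                break
        s = nxt
        path[t] = s
    return path


@njit(cache=False)
def forward_scaled(pi, A, B):
    """Scaled forward pass. ``B`` is the (L, K) per-bin emission likelihood
    (any positive per-row scaling of it is allowed). Returns (alpha, c) with
    alpha rows normalized and c the per-step scaling sums."""
    L, K = B.shape
    alpha = np.empty((L, K))
    c = np.empty(L)
    s = 0.0
    for k in range(K):
        a = pi[k] * B[0, k]
        alpha[0, k] = a
        s += a
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, L):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * A[i, j]
            a *= B[t, j]
            alpha[t, j] = a
            s += a
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s
    return alpha, c


@njit(cache=False)
def backward_scaled(A, B, c):
    """Scaled backward pass matching :func:`forward_scaled`; with this
    scaling, ``alpha * beta`` rows are already normalized posteriors."""
    L, K = B.shape
    beta = np.empty((L, K))
    for k in range(K):
        beta[L - 1, k] = 1.0
    for t in range(L - 2, -1, -1):
        for i in range(K):
            b = 0.0
            for j in range(K):
                b += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = b / c[t + 1]
    return beta


@njit(cache=False)
def transition_expectations(alpha, beta, A, B, c):
    """Accumulated expected transition counts (the EM xi sums)."""
    L, K = B.shape
    out = np.zeros((K, K))
    for t in range(L - 1):
        for i in range(K):
            ai = alpha[t, i]
            if ai == 0.0:
                continue
            for j in range(K):
                out[i, j] += ai * A[i, j] * B[t + 1, j] * beta[t + 1, j] / c[t + 1]
    return out
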