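"""Low-level HMM recursions (scaled forward-backward, Viterbi).

Kept in a separate module so the numba-compiled kernels stay tiny and
cacheable; all emission math lives in :mod:`nascenttx.segmentation`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward(b, trans, start):
    """Scaled forward-backward for one sequence.

    Parameters: ``b`` (T, S) emission likelihoods (linear scale, may be
    rescaled per row), ``trans`` (S, S) row-stochastic, ``start`` (S,).
    Returns (gamma (T, S), xi_sum (S, S), log-likelihood).
    """
    T, S = b.shape
    alpha = np.empty((T, S))
    scale = np.empty(T)
    for j in range(S):
        alpha[0, j] = start[j] * b[0, j]
    scale[0] = alpha[0].sum()
    if scale[0] <= 0:
        scale[0] = 1e-300
    alpha[0] /= scale[0]
    for t in range(1, T):
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[t - 1, i] * trans[i, j]
            alpha[t, j] = acc * b[t, j]
        scale[t] = alpha[t].sum()
        if scale[t] <= 0:
            scale[t] = 1e-300
        alpha[t] /= scale[t]

    beta = np.empty((T, S))
    beta[T - 1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(T - 2, -1, -1):
        denom = scale[t + 1]
        for i in range(S):
            acc = 0.0
            for j in range(S):
                term = trans[i, j] * b[t + 1, j] * beta[t + 1, j]
                xi_sum[i, j] += alpha[t, i] * term / denom
                acc += term
            beta[t, i] = acc / denom

    gamma = alpha * beta
    for t in range(T):
        tot = gamma[t].sum()
        if tot > 0:
            gamma[t] /= tot
    ll = np.sum(np.log(scale))
    return gamma, xi_sum, ll


@njit(cache=True)
def viterbi(logb, log_trans, log_start):
    """Most probable state path; ties resolved toward the lower state index."""
    T, S = logb.shape
    delta = np.empty((T, S))
    psi = np.zeros((T, S), dtype=np.int64)
    for j in range(S):
        delta[0, j] = log_start[j] + logb[0, j]
    for t in range(1, T):
        for j in range(S):
            best = -np.inf
            arg = 0
            for i in range(S):
                v = delta[t - 1, i] + log_trans[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for j in range(S):
        if delta[T - 1, j] > best:
            best = delta[T - 1, j]
            arg = j
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
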