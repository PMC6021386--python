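"""Sequential numerical kernels (numba-compiled).

Three O(T) passes dominate the fit: HMM forward-backward smoothing, Viterbi
decoding, and marginal inference in a block-tridiagonal Gaussian chain (the
latent-trajectory smoother).  All are written in scaled/log-space forms that
are safe for long series.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_backward_core", "viterbi_core", "chain_smoother_core"]


@njit(cache=True)
def forward_backward_core(log_b, log_pi, log_A):
    """Scaled forward-backward for an HMM with per-frame log scores.

    Returns (gamma, xi, logZ, status); status is the first frame whose
    score row underflowed to zero everywhere, or -1 on success.
    """
    T, K = log_b.shape
    b = np.empty((T, K))
    shift = np.empty(T)
    for t in range(T):
        m = log_b[t, 0]
        for k in range(1, K):
            if log_b[t, k] > m:
                m = log_b[t, k]
        shift[t] = m
        for k in range(K):
            b[t, k] = np.exp(log_b[t, k] - m)

    A = np.exp(log_A)
    pi = np.exp(log_pi)

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * b[0, k]
        s += alpha[0, k]
    if s <= 0.0 or not np.isfinite(s):
        return np.empty((0, 0)), np.empty((0, 0, 0)), 0.0, 0
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * b[t, k]
            s += alpha[t, k]
        if s <= 0.0 or not np.isfinite(s):
            return np.empty((0, 0)), np.empty((0, 0, 0)), 0.0, t
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for j in range(K):
            acc = 0.0
            for k in range(K):
                acc += A[j, k] * b[t + 1, k] * beta[t + 1, k]
            beta[t, j] = acc / c[t + 1]

    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s

    xi = np.empty((T - 1, K, K))
    for t in range(T - 1):
        s = 0.0
        for j in range(K):
            for k in range(K):
                v = alpha[t, j] * A[j, k] * b[t + 1, k] * beta[t + 1, k] / c[t + 1]
                xi[t, j, k] = v
                s += v
        for j in range(K):
            for k in range(K):
                xi[t, j, k] /= s

    logZ = 0.0
    for t in range(T):
        logZ += np.log(c[t]) + shift[t]
    return gamma, xi, logZ, -1


@njit(cache=True)
def viterbi_core(log_b, log_pi, log_A):
    """MAP state path; ties broken toward the lower state index."""
    T, K = log_b.shape
    delta = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi[k] + log_b[0, k]
    for t in range(1, T):
        for k in range(K):
            best = delta[t - 1, 0] + log_A[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + log_A[j, k]
                if v > best:
                    best = v
                    arg = j
            delta[t, k] = best + log_b[t, k]
            back[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


@njit(cache=True)
def chain_smoother_core(J_diag, J_off, h):
    """Marginal moments of a Gaussian with block-tridiagonal precision.

    Parameters: diagonal blocks ``J_diag`` (T, P, P), super-diagonal blocks
    ``J_off`` (T-1, P, P) coupling frames t and t+1, linear term ``h``
    (T, P).  Returns posterior means (T, P), marginal covariances
    (T, P, P), lag covariances Cov(x_t, x_{t+1}) (T-1, P, P) and
    log det(J).  Forward block elimination followed by the backward
    Takahashi recursion for the needed covariance blocks.
    """
    T, P, _ = J_diag.shape
    C = np.empty((T, P, P))       # Schur complements
    Cinv = np.empty((T, P, P))
    u = np.empty((T, P))
    logdet = 0.0

    C[0] = J_diag[0]
    u[0] = h[0]
    for t in range(1, T):
        B = J_off[t - 1]          # couples t-1 and t
        CiB = np.linalg.solve(C[t - 1], B)
        C[t] = J_diag[t] - B.T @ CiB
        u[t] = h[t] - CiB.T @ u[t - 1]

    mean = np.empty((T, P))
    cov = np.empty((T, P, P))
    lag = np.empty((T - 1, P, P))

    for t in range(T):
        L = np.linalg.cholesky(C[t])
        for p in range(P):
            logdet += 2.0 * np.log(L[p, p])
        Li = np.linalg.inv(L)
        Cinv[t] = Li.T @ Li

    mean[T - 1] = Cinv[T - 1] @ u[T - 1]
    cov[T - 1] = Cinv[T - 1]
    for t in range(T - 2, -1, -1):
        G = -(Cinv[t] @ J_off[t])
        mean[t] = Cinv[t] @ u[t] + G @ mean[t + 1]
        lag[t] = G @ cov[t + 1]
        cov[t] = Cinv[t] + G @ cov[t + 1] @ G.T
    return mean, cov, lag, logdet
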