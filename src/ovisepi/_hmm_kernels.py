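"""Numba kernels for the discrete-observation HMM recursions.

Observations are encoded as integer codes (the 5-bit mark pattern of a bin),
so the forward/backward recursions are those of a generic discrete HMM over
``n_codes`` symbols. Scaling follows Rabiner: alpha is normalised per
position and the log-likelihood is the sum of log normalisers.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def forward_scaled(codes, pi, A, B):
    """Scaled forward pass. Returns (alpha_hat, c, loglik)."""
    T = codes.shape[0]
    K = A.shape[0]
    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[k, codes[0]]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = acc * B[j, codes[t]]
            s += alpha[t, j]
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])
    return alpha, c, ll


@njit(cache=True)
def backward_scaled(codes, A, B, c):
    """Scaled backward pass matching forward_scaled's normalisers."""
    T = codes.shape[0]
    K = A.shape[0]
    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += A[i, j] * B[j, codes[t + 1]] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]
    return beta


@njit(cache=True)
def posterior(codes, pi, A, B):
    """Posterior state marginals gamma (T, K) and the sequence log-likelihood."""
    alpha, c, ll = forward_scaled(codes, pi, A, B)
    beta = backward_scaled(codes, A, B, c)
    T, K = alpha.shape
    gamma = np.empty((T, K))
    for t in range(T):
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
    return gamma, ll


@njit(cache=True)
def backward_loglik(codes, pi, A, B):
    """Total log-likelihood computed through the (unscaled-log) backward pass."""
    T = codes.shape[0]
    K = A.shape[0]
    # log-space backward to stay independent of the forward implementation
    logbeta = np.zeros(K)
    work = np.empty(K)
    for t in range(T - 2, -1, -1):
        newb = np.empty(K)
        for i in range(K):
            for j in range(K):
                work[j] = (np.log(A[i, j]) + np.log(B[j, codes[t + 1]])
                           + logbeta[j])
            m = work[0]
            for j in range(1, K):
                if work[j] > m:
                    m = work[j]
            acc = 0.0
            for j in range(K):
                acc += np.exp(work[j] - m)
            newb[i] = m + np.log(acc)
        logbeta = newb
    for k in range(K):
        work[k] = np.log(pi[k]) + np.log(B[k, codes[0]]) + logbeta[k]
    m = work[0]
    for k in range(1, K):
        if work[k] > m:
            m = work[k]
    acc = 0.0
    for k in range(K):
        acc += np.exp(work[k] - m)
    return m + np.log(acc)


@njit(cache=True)
def em_accumulate(codes, pi, A, B, n_codes):
    """One E-step over a sequence.

    Returns (loglik, gamma0, xi_sum, code_gamma, gamma_sum) where
    xi_sum[i, j] accumulates expected i->j transitions, code_gamma[k, code]
    the expected occupancy of state k at bins showing each code, and
    gamma_sum[k] the total occupancy.
    """
    T = codes.shape[0]
    K = A.shape[0]
    alpha, c, ll = forward_scaled(codes, pi, A, B)
    beta = backward_scaled(codes, A, B, c)
    gamma0 = np.empty(K)
    xi_sum = np.zeros((K, K))
    code_gamma = np.zeros((K, n_codes))
    gamma_sum = np.zeros(K)
    for t in range(T):
        code = codes[t]
        for k in range(K):
            g = alpha[t, k] * beta[t, k]
            code_gamma[k, code] += g
            gamma_sum[k] += g
            if t == 0:
                gamma0[k] = g
    for t in range(T - 1):
        cn = c[t + 1]
        code = codes[t + 1]
        for i in range(K):
            ai = alpha[t, i]
            for j in range(K):
                xi_sum[i, j] += (ai * A[i, j] * B[j, code]
                                 * beta[t + 1, j] / cn)
    return ll, gamma0, xi_sum, code_gamma, gamma_sum


@njit(cache=True)
def viterbi(codes, pi, A, B):
    """Most probable state path (log-space Viterbi)."""
    T = codes.shape[0]
    K = A.shape[0]
    logA = np.log(A)
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = np.log(pi[k]) + np.log(B[k, codes[0]])
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[t - 1, i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + np.log(B[j, codes[t]])
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for k in range(K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
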