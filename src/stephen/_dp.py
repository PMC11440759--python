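"""Numba kernels for the explicit-duration HSMM dynamic programmes.

All kernels work on one contiguous observation segment in the log domain.
Shapes: logb (T, K) per-minute emission log-probs; logp / logS (K, D)
sojourn log-pmf and log-survival over durations 1..D; logpi (K,) initial
log-probs; logA (K, K) transition log-probs with an effectively -inf
diagonal.  ``censored`` selects the right-censored treatment of the final
sojourn (survival instead of pmf).
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_TINY = -1e30


@njit(cache=False)
def forward(logb, logp, logS, logpi, logA, censored):
    """Forward pass: returns (loglik, alpha, in_arr, cumb).

    alpha[t, k]  = log P(obs 0..t, a sojourn of state k ends after obs t)
    in_arr[s, k] = log P(obs 0..s-1, state k starts at obs s)
    cumb[t, k]   = cumulative emission log-prob of obs 0..t-1
    """
    T, K = logb.shape
    D = logp.shape[1]
    cumb = np.zeros((T + 1, K))
    for t in range(T):
        for k in range(K):
            cumb[t + 1, k] = cumb[t, k] + logb[t, k]
    alpha = np.empty((T, K))
    in_arr = np.empty((T + 1, K))
    for k in range(K):
        in_arr[0, k] = logpi[k]
    scr = np.empty(D)
    for t in range(T):
        Dt = min(D, t + 1)
        for k in range(K):
            m = -np.inf
            for d in range(1, Dt + 1):
                s = logp[k, d - 1] + (cumb[t + 1, k] - cumb[t + 1 - d, k]) + in_arr[t + 1 - d, k]
                scr[d - 1] = s
                if s > m:
                    m = s
            if m == -np.inf or m <= LOG_TINY:
                alpha[t, k] = LOG_TINY
            else:
                tot = 0.0
                for d in range(Dt):
                    tot += np.exp(scr[d] - m)
                alpha[t, k] = m + np.log(tot)
        for k in range(K):
            m = -np.inf
            for j in range(K):
                s = alpha[t, j] + logA[j, k]
                if s > m:
                    m = s
            if m == -np.inf or m <= LOG_TINY:
                in_arr[t + 1, k] = LOG_TINY
            else:
                tot = 0.0
                for j in range(K):
                    tot += np.exp(alpha[t, j] + logA[j, k] - m)
                in_arr[t + 1, k] = m + np.log(tot)
    # terminal
    if censored:
        Ut = min(D, T)
        m = -np.inf
        for k in range(K):
            for u in range(1, Ut + 1):
                s = logS[k, u - 1] + (cumb[T, k] - cumb[T - u, k]) + in_arr[T - u, k]
                if s > m:
                    m = s
        if m == -np.inf or m <= LOG_TINY:
            ll = LOG_TINY
        else:
            tot = 0.0
            for k in range(K):
                for u in range(1, Ut + 1):
                    s = logS[k, u - 1] + (cumb[T, k] - cumb[T - u, k]) + in_arr[T - u, k]
                    tot += np.exp(s - m)
            ll = m + np.log(tot)
    else:
        m = -np.inf
        for k in range(K):
            if alpha[T - 1, k] > m:
                m = alpha[T - 1, k]
        if m == -np.inf or m <= LOG_TINY:
            ll = LOG_TINY
        else:
            tot = 0.0
            for k in range(K):
                tot += np.exp(alpha[T - 1, k] - m)
            ll = m + np.log(tot)
    return ll, alpha, in_arr, cumb


@njit(cache=False)
def backward_estep(logb, logp, logS, logpi, logA, cumb, in_arr, alpha, ll, censored):
    """Backward pass plus posterior accumulation.

    Returns (gamma, dur_w, cens_w, xi, p_start):
    gamma[t, k]    state-occupancy posterior,
    dur_w[k, d-1]  expected count of complete sojourns of duration d,
    cens_w[k, u-1] expected count of right-censored sojourns of observed
                   length u,
    xi[j, k]       expected j -> k transition count,
    p_start[k]     posterior of the segment starting in state k.
    """
    T, K = logb.shape
    D = logp.shape[1]
    u_arr = np.empty((T, K))
    beta_end = np.empty((T + 1, K))
    for k in range(K):
        beta_end[T, k] = LOG_TINY if censored else 0.0
    dur_w = np.zeros((K, D))
    cens_w = np.zeros((K, D))
    gamma_diff = np.zeros((T + 1, K))
    scr = np.empty((K, D))
    cens_term = np.empty(K)
    for t in range(T - 1, -1, -1):
        rem = T - t
        Dt = min(D, rem)
        for k in range(K):
            m = -np.inf
            for d in range(1, Dt + 1):
                e = t + d
                if e == T and censored:
                    s = -np.inf
                else:
                    s = logp[k, d - 1] + (cumb[e, k] - cumb[t, k]) + beta_end[e, k]
                scr[k, d - 1] = s
                if s > m:
                    m = s
            if censored and rem <= D:
                ct = logS[k, rem - 1] + (cumb[T, k] - cumb[t, k])
            else:
                ct = -np.inf
            cens_term[k] = ct
            if ct > m:
                m = ct
            if m == -np.inf or m <= LOG_TINY:
                u_arr[t, k] = LOG_TINY
            else:
                tot = 0.0
                for d in range(Dt):
                    if scr[k, d] > -np.inf:
                        tot += np.exp(scr[k, d] - m)
                if ct > -np.inf:
                    tot += np.exp(ct - m)
                u_arr[t, k] = m + np.log(tot)
        for j in range(K):
            m = -np.inf
            for k in range(K):
                s = logA[j, k] + u_arr[t, k]
                if s > m:
                    m = s
            if m == -np.inf or m <= LOG_TINY:
                beta_end[t, j] = LOG_TINY
            else:
                tot = 0.0
                for k in range(K):
                    tot += np.exp(logA[j, k] + u_arr[t, k] - m)
                beta_end[t, j] = m + np.log(tot)
        # posteriors of sojourns starting at t
        for k in range(K):
            base = in_arr[t, k] - ll
            arrive = 0.0
            for d in range(1, Dt + 1):
                if scr[k, d - 1] > LOG_TINY:
                    eta = np.exp(base + scr[k, d - 1])
                    dur_w[k, d - 1] += eta
                    gamma_diff[t + d, k] -= eta
                    arrive += eta
            if cens_term[k] > LOG_TINY:
                rho = np.exp(base + cens_term[k])
                cens_w[k, rem - 1] += rho
                arrive += rho
            gamma_diff[t, k] += arrive
    gamma = np.empty((T, K))
    for k in range(K):
        acc = 0.0
        for t in range(T):
            acc += gamma_diff[t, k]
            gamma[t, k] = acc
    xi = np.zeros((K, K))
    for t in range(T - 1):
        for j in range(K):
            for k in range(K):
                s = alpha[t, j] + logA[j, k] + u_arr[t + 1, k] - ll
                if s > -600.0:
                    xi[j, k] += np.exp(s)
    p_start = np.empty(K)
    for k in range(K):
        p_start[k] = np.exp(logpi[k] + u_arr[0, k] - ll)
    return gamma, dur_w, cens_w, xi, p_start


@njit(cache=False)
def viterbi_path(logb, logp, logS, logpi, logA, censored):
    """Most probable (state, duration) segmentation, expanded to minutes.

    Ties break toward the lower state index, then the shorter duration
    (strict improvement required, candidates scanned in that order).
    Returns 0-based state indices.
    """
    T, K = logb.shape
    D = logp.shape[1]
    cumb = np.zeros((T + 1, K))
    for t in range(T):
        for k in range(K):
            cumb[t + 1, k] = cumb[t, k] + logb[t, k]
    delta = np.empty((T, K))
    best_d = np.zeros((T, K), dtype=np.int64)
    maxin = np.empty((T + 1, K))
    argin = np.full((T + 1, K), -1, dtype=np.int64)
    for k in range(K):
        maxin[0, k] = logpi[k]
    for t in range(T):
        Dt = min(D, t + 1)
        for k in range(K):
            m = -np.inf
            bd = 1
            for d in range(1, Dt + 1):
                s = logp[k, d - 1] + (cumb[t + 1, k] - cumb[t + 1 - d, k]) + maxin[t + 1 - d, k]
                if s > m:
                    m = s
                    bd = d
            delta[t, k] = m
            best_d[t, k] = bd
        for k in range(K):
            m = -np.inf
            bj = 0
            for j in range(K):
                s = delta[t, j] + logA[j, k]
                if s > m:
                    m = s
                    bj = j
            maxin[t + 1, k] = m
            argin[t + 1, k] = bj
    # terminal: lowest state first, then shortest remaining duration
    k_last = 0
    d_last = 1
    m = -np.inf
    if censored:
        Ut = min(D, T)
        for k in range(K):
            for u in range(1, Ut + 1):
                s = logS[k, u - 1] + (cumb[T, k] - cumb[T - u, k]) + maxin[T - u, k]
                if s > m:
                    m = s
                    k_last = k
                    d_last = u
    else:
        for k in range(K):
            if delta[T - 1, k] > m:
                m = delta[T - 1, k]
                k_last = k
        d_last = best_d[T - 1, k_last]
    path = np.empty(T, dtype=np.int64)
    k = k_last
    d = d_last
    t_end = T
    while True:
        for i in range(t_end - d, t_end):
            path[i] = k
        t_start = t_end - d
        if t_start == 0:
            break
        k = argin[t_start, k]
        t_end = t_start
        d = best_d[t_start - 1, k]
    return path
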