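"""Independent brute-force oracles used to check the dynamic programmes.

These deliberately share no code with the package internals beyond the
parameter tables: the likelihood and Viterbi oracles enumerate every valid
(state, duration) segmentation recursively, and the weighted-median oracle
scans candidate durations directly against the defining property.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from stephen.hsmm import HsmmModel, _emission_matrix, _log_tables


def enumerate_loglik(model: HsmmModel, steps, hr, censor_last: bool = True) -> float:
    """Log-likelihood by exhaustive enumeration of segmentations."""
    T = len(steps)
    logp, logS, logpi, logA = _log_tables(model)
    logb = _emission_matrix(
        model, np.asarray(steps), None if hr is None else np.asarray(hr)
    )
    terms: list[float] = []

    def rec(t: int, prev, acc: float) -> None:
        for k in range(model.K):
            if k == prev:
                continue
            trans = logpi[k] if prev is None else logA[prev, k]
            for d in range(1, model.d_max + 1):
                if t + d > T:
                    break
                emit = logb[t : t + d, k].sum()
                if t + d == T:
                    dur = logS[k, d - 1] if censor_last else logp[k, d - 1]
                    terms.append(acc + trans + dur + emit)
                else:
                    rec(t + d, k, acc + trans + logp[k, d - 1] + emit)

    rec(0, None, 0.0)
    return float(logsumexp(terms)) if terms else -np.inf


def enumerate_viterbi(model: HsmmModel, steps, hr, censor_last: bool = True):
    """(best score, best path) by exhaustive enumeration of segmentations."""
    T = len(steps)
    logp, logS, logpi, logA = _log_tables(model)
    logb = _emission_matrix(
        model, np.asarray(steps), None if hr is None else np.asarray(hr)
    )
    best = [-np.inf, None]

    def rec(t: int, prev, acc: float, path: list[int]) -> None:
        for k in range(model.K):
            if k == prev:
                continue
            trans = logpi[k] if prev is None else logA[prev, k]
            for d in range(1, model.d_max + 1):
                if t + d > T:
                    break
                emit = logb[t : t + d, k].sum()
                if t + d == T:
                    dur = logS[k, d - 1] if censor_last else logp[k, d - 1]
                    score = acc + trans + dur + emit
                    if score > best[0]:
                        best[0] = score
                        best[1] = path + [k + 1] * d
                else:
                    rec(t + d, k, acc + trans + logp[k, d - 1] + emit, path + [k + 1] * d)

    rec(0, None, 0.0, [])
    return best[0], (None if best[1] is None else np.array(best[1]))


def path_score(model: HsmmModel, path, steps, hr, censor_last: bool = True) -> float:
    """Joint log-probability of a given per-minute state path (1-based)."""
    logp, logS, logpi, logA = _log_tables(model)
    logb = _emission_matrix(
        model, np.asarray(steps), None if hr is None else np.asarray(hr)
    )
    score = 0.0
    prev = None
    i = 0
    T = len(path)
    while i < T:
        j = i
        while j < T and path[j] == path[i]:
            j += 1
        k = path[i] - 1
        d = j - i
        score += (logpi[k] if prev is None else logA[prev, k]) + logb[i:j, k].sum()
        score += logS[k, d - 1] if (j == T and censor_last) else logp[k, d - 1]
        prev = k
        i = j
    return float(score)


def random_model(rng: np.random.Generator, K: int, d_max: int, use_hr: bool) -> HsmmModel:
    """A random valid model for property tests."""
    from stephen.hsmm import NbParams, SojournParams

    step_p = [NbParams(float(rng.uniform(0.1, 50)), float(rng.uniform(0.3, 20))) for _ in range(K)]
    hr_p = (
        [NbParams(float(rng.uniform(50, 130)), float(rng.uniform(5, 50))) for _ in range(K)]
        if use_hr
        else None
    )
    soj = [
        SojournParams(float(rng.uniform(0.5, 4)), float(rng.uniform(0.5, 4)), d_max=d_max)
        for _ in range(K)
    ]
    init = rng.dirichlet(np.ones(K))
    if K > 1:
        rows = rng.dirichlet(np.ones(K - 1), size=K)
        trans = np.zeros((K, K))
        for i in range(K):
            trans[i, [j for j in range(K) if j != i]] = rows[i]
    else:
        trans = np.zeros((1, 1))
    return HsmmModel(
        K=K, step_params=step_p, hr_params=hr_p, sojourn=soj, init_probs=init, trans=trans
    )


def weighted_median_oracle(durations) -> float:
    """Smallest bout duration at which cumulative sorted time reaches half."""
    d = np.sort(np.asarray(durations, dtype=float))
    half = d.sum() / 2.0
    acc = 0.0
    for v in d:
        acc += v
        if acc >= half:
            return float(v)
    return float(d[-1])
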