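"""Explicit-duration hidden semi-Markov model with Negative Binomial emissions.

The model: K latent activity states; while in state k the per-minute step
count (and optionally heart rate) is Negative Binomial with state-specific
mean/dispersion; the sojourn (number of consecutive minutes spent in the
state) follows a Gamma distribution discretised onto {1, ..., d_max}; on
leaving a state the next state is drawn from a zero-diagonal row-stochastic
transition matrix.  Compared with a plain HMM's geometric sojourns, the Gamma
sojourn lets the model represent persistent bouts — long sedentary or
standing spells — directly.

The NB parameterisation is (mean mu, dispersion r) with
variance = mu + mu^2 / r, so large r approaches Poisson.

Observation sequences are handled as *segments*: maximal runs of contiguous
minutes (non-wear gaps split the stream).  Each segment restarts from the
initial state distribution.  By default the final sojourn of each segment is
treated as right-censored: it contributes a survival probability
P(D >= observed remaining length) rather than a pmf term, which avoids
penalising long bouts that were still in progress when the record ended.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, stats
from scipy.cluster.vq import kmeans2

from . import _dp
from .errors import InsufficientDataError, NumericalError

MEAN_FLOOR = 1e-3
DISPERSION_BOUNDS = (1e-2, 1e6)
_LOG_TINY = -1e30


@dataclass(frozen=True)
class NbParams:
    """Negative Binomial parameters: mean > 0 and dispersion (size) r > 0."""

    mean: float
    dispersion: float

    def __post_init__(self) -> None:
        if not (self.mean > 0 and np.isfinite(self.mean)):
            raise ValueError(f"NB mean must be positive, got {self.mean}")
        if not (self.dispersion > 0 and np.isfinite(self.dispersion)):
            raise ValueError(f"NB dispersion must be positive, got {self.dispersion}")


@dataclass(frozen=True)
class SojournParams:
    """Gamma sojourn parameters (shape, scale in minutes) truncated at d_max."""

    shape: float
    scale: float
    d_max: int = 240

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("Gamma shape and scale must be positive")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")

    @property
    def mean(self) -> float:
        """Untruncated Gamma mean (minutes)."""
        return self.shape * self.scale


def nb_log_pmf(x, params: NbParams):
    """Log pmf of the Negative Binomial in mean/dispersion form.

    P(X = x) with E X = mean and Var X = mean + mean^2 / dispersion.
    """
    x = np.asarray(x)
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("NB support is the non-negative integers")
    r = params.dispersion
    p = r / (r + params.mean)
    out = stats.nbinom.logpmf(np.round(x).astype(np.int64), r, p)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def sojourn_pmf(params: SojournParams) -> np.ndarray:
    """Discretised, truncated sojourn pmf over durations 1..d_max.

    p(d) is proportional to F(d) - F(d-1) for the Gamma CDF F, renormalised
    to sum to one over the truncation window.
    """
    d = np.arange(params.d_max + 1, dtype=float)
    cdf = stats.gamma.cdf(d, a=params.shape, scale=params.scale)
    pmf = np.diff(cdf)
    total = pmf.sum()
    if total <= 0:
        # all mass beyond d_max: fall back to a point mass on d_max
        pmf = np.zeros(params.d_max)
        pmf[-1] = 1.0
        return pmf
    return pmf / total


def sojourn_mean(params: SojournParams) -> float:
    """Mean of the discretised, truncated sojourn distribution (minutes)."""
    p = sojourn_pmf(params)
    return float(np.arange(1, params.d_max + 1) @ p)


@dataclass
class HsmmModel:
    """Parameter set of a K-state explicit-duration HSMM."""

    K: int
    step_params: list[NbParams]
    sojourn: list[SojournParams]
    init_probs: np.ndarray
    trans: np.ndarray
    hr_params: list[NbParams] | None = None

    def __post_init__(self) -> None:
        self.init_probs = np.asarray(self.init_probs, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.validate()

    @property
    def use_hr(self) -> bool:
        return self.hr_params is not None

    @property
    def d_max(self) -> int:
        return max(s.d_max for s in self.sojourn)

    def validate(self) -> None:
        K = self.K
        if len(self.step_params) != K or len(self.sojourn) != K:
            raise ValueError("parameter lists must have length K")
        if self.hr_params is not None and len(self.hr_params) != K:
            raise ValueError("hr_params must have length K")
        if self.init_probs.shape != (K,) or abs(self.init_probs.sum() - 1) > 1e-10:
            raise ValueError("init_probs must be a length-K simplex")
        if self.trans.shape != (K, K):
            raise ValueError("trans must be K x K")
        if np.abs(np.diag(self.trans)).max() > 0:
            raise ValueError("trans must have a zero diagonal")
        if K > 1 and np.abs(self.trans.sum(axis=1) - 1).max() > 1e-10:
            raise ValueError("trans rows must sum to 1")

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "use_hr": self.use_hr,
            "d_max": self.d_max,
            "step_params": [{"mean": p.mean, "dispersion": p.dispersion} for p in self.step_params],
            "hr_params": None
            if self.hr_params is None
            else [{"mean": p.mean, "dispersion": p.dispersion} for p in self.hr_params],
            "sojourn": [
                {"shape": s.shape, "scale": s.scale, "d_max": s.d_max} for s in self.sojourn
            ],
            "init_probs": self.init_probs.tolist(),
            "trans": self.trans.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HsmmModel":
        return cls(
            K=d["K"],
            step_params=[NbParams(**p) for p in d["step_params"]],
            hr_params=None if d.get("hr_params") is None else [NbParams(**p) for p in d["hr_params"]],
            sojourn=[SojournParams(**s) for s in d["sojourn"]],
            init_probs=np.array(d["init_probs"], dtype=float),
            trans=np.array(d["trans"], dtype=float),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HsmmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ObservationSegments:
    """Contiguous observation runs: per segment, steps (int) and optional HR.

    Heart rate is rounded to the nearest non-negative integer on construction
    so it can be evaluated under the NB emission.
    """

    steps: list[np.ndarray]
    hr: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.steps = [np.asarray(s, dtype=np.int64) for s in self.steps]
        if any(len(s) < 1 for s in self.steps):
            raise ValueError("segments must be non-empty")
        if self.hr is not None:
            self.hr = [np.maximum(0, np.round(np.asarray(h, dtype=float))).astype(np.int64) for h in self.hr]
            if [len(h) for h in self.hr] != [len(s) for s in self.steps]:
                raise ValueError("hr segments must match steps segments in length")

    @property
    def n_obs(self) -> int:
        return sum(len(s) for s in self.steps)

    @classmethod
    def from_minute_series(cls, series, use_hr: bool = True) -> "ObservationSegments":
        """Split a worn-filtered MinuteSeries at timestamp gaps into runs."""
        ts = series.timestamps
        if len(ts) == 0:
            raise InsufficientDataError("empty minute series")
        breaks = np.flatnonzero(np.diff(ts.asi8) != 60_000_000_000) + 1
        steps = np.round(series.steps).astype(np.int64)
        chunks_s = np.split(steps, breaks)
        if use_hr:
            chunks_h = np.split(series.heart_rate, breaks)
            return cls(steps=chunks_s, hr=[np.asarray(h) for h in chunks_h])
        return cls(steps=chunks_s, hr=None)


def emission_log_prob(steps: int, hr, state: int, model: HsmmModel) -> float:
    """Log emission probability of one minute under one state (0-based index).

    Steps and heart rate are conditionally independent given the state, so
    the bivariate log-probability is the sum of the two marginal NB terms.
    """
    val = nb_log_pmf(steps, model.step_params[state])
    if model.use_hr:
        if hr is None:
            raise ValueError("model uses heart rate but hr is absent")
        val += nb_log_pmf(int(round(hr)), model.hr_params[state])
    elif hr is not None:
        pass  # steps-only model ignores HR
    return float(val)


def _emission_matrix(model: HsmmModel, steps: np.ndarray, hr: np.ndarray | None) -> np.ndarray:
    """(T, K) matrix of per-minute log emission probabilities."""
    T = len(steps)
    logb = np.empty((T, K := model.K))
    for k in range(K):
        p = model.step_params[k]
        logb[:, k] = stats.nbinom.logpmf(steps, p.dispersion, p.dispersion / (p.dispersion + p.mean))
        if model.use_hr:
            q = model.hr_params[k]
            logb[:, k] += stats.nbinom.logpmf(hr, q.dispersion, q.dispersion / (q.dispersion + q.mean))
    return logb


def _log_tables(model: HsmmModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """log sojourn pmf (K, D), log survival (K, D), log init, log trans."""
    D = model.d_max
    logp = np.full((model.K, D), _LOG_TINY)
    logS = np.full((model.K, D), _LOG_TINY)
    for k, s in enumerate(model.sojourn):
        pmf = np.zeros(D)
        pmf[: s.d_max] = sojourn_pmf(s)
        surv = np.cumsum(pmf[::-1])[::-1]  # surv[d-1] = P(D >= d)
        with np.errstate(divide="ignore"):
            logp[k] = np.where(pmf > 0, np.log(np.maximum(pmf, 1e-300)), _LOG_TINY)
            logS[k] = np.where(surv > 0, np.log(np.maximum(surv, 1e-300)), _LOG_TINY)
    with np.errstate(divide="ignore"):
        logpi = np.where(model.init_probs > 0, np.log(np.maximum(model.init_probs, 1e-300)), _LOG_TINY)
        logA = np.where(model.trans > 0, np.log(np.maximum(model.trans, 1e-300)), _LOG_TINY)
    np.fill_diagonal(logA, _LOG_TINY)
    return logp, logS, logpi, logA


def _forward(logb, logp, logS, logpi, logA, censor_last: bool):
    """Forward pass on one segment (see :mod:`stephen._dp` for semantics)."""
    ll, alpha, in_arr, cumb = _dp.forward(
        np.ascontiguousarray(logb), logp, logS, logpi, logA, censor_last
    )
    return float(ll), alpha, in_arr, cumb


def log_likelihood(
    model: HsmmModel, segments: ObservationSegments, censor_last: bool = True
) -> float:
    """Explicit-duration forward log-likelihood summed over segments."""
    if model.d_max < 1:
        raise ValueError("d_max must be >= 1")
    logp, logS, logpi, logA = _log_tables(model)
    total = 0.0
    for i, steps in enumerate(segments.steps):
        hr = segments.hr[i] if segments.hr is not None else None
        logb = _emission_matrix(model, steps, hr)
        ll, *_ = _forward(logb, logp, logS, logpi, logA, censor_last)
        total += ll
    if not np.isfinite(total):
        raise NumericalError("non-finite log-likelihood")
    return total


def _backward_estep(logb, logp, logS, logpi, logA, cumb, in_arr, alpha, ll, censor_last):
    """Backward pass + posterior accumulation (see :mod:`stephen._dp`)."""
    return _dp.backward_estep(
        np.ascontiguousarray(logb), logp, logS, logpi, logA,
        cumb, in_arr, alpha, ll, censor_last,
    )


def _weighted_nb_mle(values: np.ndarray, weights: np.ndarray, current: NbParams) -> NbParams:
    """Weighted NB maximum likelihood: closed-form mean, 1-D search for dispersion.

    Keeps the better of the current and optimised dispersion so the EM
    objective never decreases.
    """
    wsum = weights.sum()
    if wsum <= 1e-10:
        return current
    counts = np.bincount(values, weights=weights)
    support = np.flatnonzero(counts > 0)
    w = counts[support]
    mu = max(MEAN_FLOOR, float(support @ w / wsum))

    def negq(logr: float) -> float:
        r = np.exp(logr)
        return -float(w @ stats.nbinom.logpmf(support, r, r / (r + mu)))

    lo, hi = np.log(DISPERSION_BOUNDS[0]), np.log(DISPERSION_BOUNDS[1])
    res = optimize.minimize_scalar(negq, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-4})
    r_cur = float(np.clip(current.dispersion, *DISPERSION_BOUNDS))
    best_r = float(np.exp(res.x)) if res.fun <= negq(np.log(r_cur)) else r_cur
    return NbParams(mean=mu, dispersion=best_r)


def _weighted_sojourn_mle(
    dur_w: np.ndarray, cens_w: np.ndarray, current: SojournParams
) -> SojournParams:
    """Maximise the expected sojourn log-likelihood over (shape, scale).

    Complete sojourns contribute pmf terms, censored ones survival terms.
    Starts from the current parameters; keeps the better point.
    """
    D = current.d_max
    if dur_w.sum() + cens_w.sum() <= 1e-10:
        return current

    dd = np.arange(D + 1, dtype=float)

    def negq(x: np.ndarray) -> float:
        shape, scale = np.exp(x)
        if not (np.isfinite(shape) and np.isfinite(scale)):
            return np.inf
        cdf = stats.gamma.cdf(dd, a=shape, scale=scale)
        pmf = np.diff(cdf)
        tot = pmf.sum()
        if tot <= 0:
            return np.inf
        pmf = pmf / tot
        surv = np.cumsum(pmf[::-1])[::-1]
        logpmf = np.log(np.maximum(pmf, 1e-300))
        logsurv = np.log(np.maximum(surv, 1e-300))
        return -float(dur_w @ logpmf + cens_w @ logsurv)

    x0 = np.log([current.shape, current.scale])
    res = optimize.minimize(negq, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 200})
    if res.fun < negq(x0):
        shape, scale = np.exp(res.x)
        return SojournParams(shape=float(shape), scale=float(scale), d_max=D)
    return current


def _auto_init(
    segments: ObservationSegments, K: int, use_hr: bool, d_max: int, rng: np.random.Generator,
    jitter: bool, strategy: str = "spread",
) -> HsmmModel:
    """Moment-based initial model from a partition of the observations.

    Observations are grouped on log1p(steps) alone — step count is the
    intensity signature, while per-minute HR is noisy enough to swamp the
    rare high-intensity minutes.  ``strategy="spread"`` assigns each minute
    to the nearest of K centres evenly spaced across the log-step *range*
    (deterministic; mass-weighted centres would merge the rare top states
    into the heavy low-step mass).  ``strategy="kmeans"`` draws k-means++
    centres under ``rng`` with a couple of Lloyd steps, supplying restart
    diversity.  Per-group moment estimates seed the NB parameters and run
    lengths of the group labels seed the sojourn moments.
    """
    steps = np.concatenate(segments.steps)
    hr = np.concatenate(segments.hr) if use_hr else None
    # group on a 3-minute running median of the step counts: activity states
    # persist for minutes, so isolated spurious step bursts inside sedentary
    # runs are assigned to their neighbourhood and the moment estimates
    # (taken from the raw values) absorb them into a heavy-tailed state
    smooth = np.concatenate(
        [ndimage.median_filter(s.astype(float), size=3, mode="nearest") for s in segments.steps]
    )
    X = np.log1p(smooth)[:, None]
    order = np.lexsort((hr, steps)) if use_hr else np.argsort(steps, kind="stable")
    if strategy == "spread":
        lo, hi = float(X.min()), float(X.max())
        centres = lo + (np.arange(K) + 0.5) / K * max(hi - lo, 1e-6)
        labels = np.argmin(np.abs(X - centres[None, :]), axis=1)
    else:
        _, labels = kmeans2(X, K, iter=2, minit="++", seed=rng)
    for k in range(K):  # re-seat any empty group on a quantile group
        if not (labels == k).any():
            labels[np.array_split(order, K)[k]] = k

    def nb_moments(x: np.ndarray) -> NbParams:
        mu = max(MEAN_FLOOR, float(np.mean(x)))
        var = float(np.var(x))
        if jitter:
            mu = max(MEAN_FLOOR, mu * rng.uniform(0.8, 1.25))
        r = mu**2 / (var - mu) if var > mu * 1.0001 else DISPERSION_BOUNDS[1] / 100
        return NbParams(mean=mu, dispersion=float(np.clip(r, *DISPERSION_BOUNDS)))

    step_params = [nb_moments(steps[labels == k]) for k in range(K)]
    hr_params = [nb_moments(hr[labels == k]) for k in range(K)] if use_hr else None

    # sojourn moments from run lengths of the quantile labels within segments
    sojourn = []
    off = 0
    runs_by_state: list[list[int]] = [[] for _ in range(K)]
    for seg in segments.steps:
        lab = labels[off : off + len(seg)]
        off += len(seg)
        start = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[start]:
                runs_by_state[lab[start]].append(i - start)
                start = i
    for k in range(K):
        runs = np.array(runs_by_state[k] or [2.0], dtype=float)
        m = max(1.0, float(runs.mean()))
        v = max(0.25, float(runs.var()))
        scale = max(0.2, v / m)
        shape = max(0.2, m / scale)
        sojourn.append(SojournParams(shape=shape, scale=scale, d_max=d_max))

    init = np.full(K, 1.0 / K)
    if K > 1:
        trans = np.full((K, K), 1.0 / (K - 1))
        np.fill_diagonal(trans, 0.0)
    else:
        trans = np.zeros((1, 1))
    return HsmmModel(K=K, step_params=step_params, hr_params=hr_params,
                     sojourn=sojourn, init_probs=init, trans=trans)


def _em_once(
    segments: ObservationSegments,
    model: HsmmModel,
    tol: float,
    max_iter: int,
    censor_last: bool,
) -> tuple[HsmmModel, list[float]]:
    trace: list[float] = []
    K = model.K
    for _ in range(max_iter):
        logp, logS, logpi, logA = _log_tables(model)
        D = logp.shape[1]
        ll_total = 0.0
        gamma_all = []
        dur_w = np.zeros((K, D))
        cens_w = np.zeros((K, D))
        xi = np.zeros((K, K))
        p_start = np.zeros(K)
        for i, stp in enumerate(segments.steps):
            hr = segments.hr[i] if segments.hr is not None else None
            logb = _emission_matrix(model, stp, hr)
            ll, alpha, in_arr, cumb = _forward(logb, logp, logS, logpi, logA, censor_last)
            if not np.isfinite(ll):
                raise NumericalError("non-finite segment log-likelihood during EM")
            g, dw, cw, x, ps = _backward_estep(
                logb, logp, logS, logpi, logA, cumb, in_arr, alpha, ll, censor_last
            )
            ll_total += ll
            gamma_all.append(g)
            dur_w += dw
            cens_w += cw[:, :D]
            xi += x
            p_start += ps
        trace.append(ll_total)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1.0 + abs(trace[-2])):
            break

        gamma = np.vstack(gamma_all)
        steps_all = np.concatenate(segments.steps)
        hr_all = np.concatenate(segments.hr) if segments.hr is not None else None

        new_step = [
            _weighted_nb_mle(steps_all, gamma[:, k], model.step_params[k]) for k in range(K)
        ]
        new_hr = (
            [_weighted_nb_mle(hr_all, gamma[:, k], model.hr_params[k]) for k in range(K)]
            if model.use_hr
            else None
        )
        new_soj = [
            _weighted_sojourn_mle(dur_w[k], cens_w[k], model.sojourn[k]) for k in range(K)
        ]
        ps_sum = p_start.sum()
        new_init = p_start / ps_sum if ps_sum > 0 else model.init_probs
        if K > 1:
            np.fill_diagonal(xi, 0.0)
            rows = xi.sum(axis=1, keepdims=True)
            new_trans = np.where(rows > 1e-12, xi / np.maximum(rows, 1e-300), model.trans)
            new_trans = new_trans / new_trans.sum(axis=1, keepdims=True)
            np.fill_diagonal(new_trans, 0.0)
            new_trans = new_trans / new_trans.sum(axis=1, keepdims=True)
        else:
            new_trans = model.trans
        model = HsmmModel(
            K=K, step_params=new_step, hr_params=new_hr, sojourn=new_soj,
            init_probs=new_init, trans=new_trans,
        )
    return model, trace


def fit_em(
    segments: ObservationSegments,
    K: int,
    use_hr: bool,
    init: HsmmModel | str = "auto",
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    n_restarts: int = 3,
    d_max: int = 240,
    censor_last: bool = True,
) -> tuple[HsmmModel, list[float]]:
    """Fit an HSMM by EM; returns the best restart and its log-likelihood trace.

    The first restart starts from quantile-group moment estimates; further
    restarts jitter the group means multiplicatively under ``seed``.  The
    returned trace is non-decreasing up to a small numerical tolerance.
    """
    if use_hr and segments.hr is None:
        raise ValueError("use_hr=True but segments carry no heart rate")
    if segments.n_obs < 10 * K:
        raise InsufficientDataError(
            f"need at least {10 * K} observations for K={K}, got {segments.n_obs}"
        )
    rng = np.random.default_rng(seed)
    best: tuple[HsmmModel, list[float]] | None = None
    for restart in range(max(1, n_restarts)):
        if isinstance(init, HsmmModel):
            model0 = init
        else:
            model0 = _auto_init(
                segments, K, use_hr, d_max, rng, jitter=restart > 0,
                strategy="spread" if restart == 0 else "kmeans",
            )
        try:
            model, trace = _em_once(segments, model0, tol, max_iter, censor_last)
        except NumericalError:
            if isinstance(init, HsmmModel):
                raise
            warnings.warn(f"restart {restart} failed numerically; skipped", stacklevel=2)
            continue
        if best is None or trace[-1] > best[1][-1]:
            best = (model, trace)
        if isinstance(init, HsmmModel):
            break
    if best is None:
        raise NumericalError("all EM restarts failed")
    return best


def viterbi(
    model: HsmmModel, segments: ObservationSegments, censor_last: bool = True
) -> np.ndarray:
    """Most probable (state, duration) segmentation, expanded to minutes.

    Returns 1-based state indices, concatenated across segments.  Ties are
    broken toward the lower state index, then the shorter duration, so the
    decoding is deterministic.
    """
    logp, logS, logpi, logA = _log_tables(model)
    out = []
    for i, steps in enumerate(segments.steps):
        hr = segments.hr[i] if segments.hr is not None else None
        logb = _emission_matrix(model, steps, hr)
        out.append(_viterbi_one(logb, logp, logS, logpi, logA, censor_last))
    return np.concatenate(out)


def _viterbi_one(logb, logp, logS, logpi, logA, censor_last) -> np.ndarray:
    path = _dp.viterbi_path(
        np.ascontiguousarray(logb), logp, logS, logpi, logA, censor_last
    )
    return path + 1
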