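"""Synthetic cohorts of paired wearable minute data and posture events.

The generator is the study's controlled stand-in for free-living device
data: a 4-state semi-Markov activity process (sedentary, standing/LPA, MPA,
VPA) emits NB-distributed step counts and heart rate per minute with Gamma
sojourns; subjects differ by a resting-heart-rate offset; non-wear gaps are
carved out as zero-HR runs; and sedentary minutes can be contaminated with
spurious step bursts that leave heart rate untouched — the wrist-movement
artefact (laundry folding, gaming) that motivates using heart rate at all.
A posture-events referent stream is derived from the true labels (sitting =
sedentary, standing = standing/LPA, stepping = MPA/VPA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import ActivityLabel
from .hsmm import HsmmModel, NbParams, SojournParams, sojourn_pmf
from .io import EventSeries, MinuteSeries, write_events_csv, write_minute_csv

#: default 4-state cohort: step/min means well separated across intensity,
#: heart-rate means rising with intensity, sojourn means in minutes.
DEFAULT_STEP_PARAMS = [
    NbParams(0.2, 0.5),
    NbParams(5.0, 1.0),
    NbParams(40.0, 5.0),
    NbParams(110.0, 10.0),
]
DEFAULT_HR_PARAMS = [
    NbParams(65.0, 30.0),
    NbParams(75.0, 30.0),
    NbParams(95.0, 30.0),
    NbParams(120.0, 30.0),
]
DEFAULT_SOJOURN = [  # means 25, 10, 8, 4 min
    SojournParams(2.5, 10.0, d_max=60),
    SojournParams(2.0, 5.0, d_max=60),
    SojournParams(2.0, 4.0, d_max=60),
    SojournParams(1.5, 8.0 / 3.0, d_max=60),
]
DEFAULT_TRANS = np.array(
    [
        [0.0, 0.70, 0.25, 0.05],
        [0.60, 0.0, 0.35, 0.05],
        [0.20, 0.60, 0.0, 0.20],
        [0.05, 0.25, 0.70, 0.0],
    ]
)
DEFAULT_INIT = np.array([0.40, 0.30, 0.20, 0.10])


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic subject."""

    K: int = 4
    step_params: list[NbParams] = field(default_factory=lambda: list(DEFAULT_STEP_PARAMS))
    hr_params: list[NbParams] = field(default_factory=lambda: list(DEFAULT_HR_PARAMS))
    sojourn: list[SojournParams] = field(default_factory=lambda: list(DEFAULT_SOJOURN))
    init_probs: np.ndarray = field(default_factory=lambda: DEFAULT_INIT.copy())
    trans: np.ndarray = field(default_factory=lambda: DEFAULT_TRANS.copy())
    days: int = 2
    minutes_per_day: int = 960  # 06:00-22:00 awake wear
    day_start_hour: int = 6
    resting_hr_offset: float = 0.0
    spurious_prob: float = 0.0
    spurious_steps: NbParams = field(default_factory=lambda: NbParams(30.0, 2.0))
    nonwear_gap_rate: float = 1.0  # expected gaps per day
    nonwear_gap_mean_minutes: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.init_probs = np.asarray(self.init_probs, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if not 0.0 <= self.spurious_prob <= 1.0:
            raise ValueError("spurious_prob must lie in [0, 1]")
        for name in ("step_params", "hr_params", "sojourn"):
            if len(getattr(self, name)) != self.K:
                raise ValueError(f"{name} must have length K={self.K}")

    def true_model(self, use_hr: bool = True) -> HsmmModel:
        """The generating parameters as an HsmmModel (for oracle comparisons)."""
        return HsmmModel(
            K=self.K,
            step_params=list(self.step_params),
            hr_params=list(self.hr_params) if use_hr else None,
            sojourn=list(self.sojourn),
            init_probs=self.init_probs.copy(),
            trans=self.trans.copy(),
        )


@dataclass
class SimulatedSubject:
    """Ground truth plus device-like and referent-like views of one subject."""

    subject_id: str
    true_states: np.ndarray  # 1-based, full minute grid
    true_labels: np.ndarray  # ActivityLabel values
    minutes: MinuteSeries  # device-like; non-wear gaps appear as HR = 0
    events: EventSeries  # posture referent built from the true labels
    config: SimulationConfig
    seed: int


def _nb_draw(rng: np.random.Generator, params: NbParams, size) -> np.ndarray:
    p = params.dispersion / (params.dispersion + params.mean)
    return rng.negative_binomial(params.dispersion, p, size=size)


def _label_order(config: SimulationConfig) -> np.ndarray:
    """Rank of each state by (step mean, HR mean): rank 0 = sedentary."""
    keys = [(config.step_params[k].mean, config.hr_params[k].mean) for k in range(config.K)]
    order = sorted(range(config.K), key=lambda k: keys[k])
    ranks = np.empty(config.K, dtype=np.int64)
    for rank, state in enumerate(order):
        ranks[state] = rank
    return ranks


def _minute_grid(config: SimulationConfig, origin: str = "2024-01-01") -> pd.DatetimeIndex:
    start = pd.Timestamp(origin) + pd.Timedelta(hours=config.day_start_hour)
    days = [
        pd.date_range(start + pd.Timedelta(days=d), periods=config.minutes_per_day, freq="min")
        for d in range(config.days)
    ]
    return pd.DatetimeIndex(np.concatenate([d.asi8 for d in days]).view("datetime64[ns]"))


def _events_from_labels(
    subject_id: str, grid: pd.DatetimeIndex, labels: np.ndarray
) -> EventSeries:
    """Merge consecutive same-label minutes into posture events.

    Sitting = sedentary, standing = standing/LPA, stepping = MPA or VPA.
    Events break at day boundaries (grid gaps).
    """
    act = np.where(
        labels == int(ActivityLabel.SEDENTARY),
        0,
        np.where(labels == int(ActivityLabel.STANDING_LPA), 1, 2),
    )
    names = np.array(["sitting", "standing", "stepping"])
    ts = grid.asi8
    contiguous = np.diff(ts) == 60_000_000_000
    breaks = np.flatnonzero((act[1:] != act[:-1]) | ~contiguous) + 1
    bounds = np.concatenate([[0], breaks, [len(act)]])
    rows = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        rows.append(
            {
                "start": grid[s],
                "duration_s": round((e - s) * 60.0, 1),
                "activity": names[act[s]],
            }
        )
    return EventSeries(subject_id, pd.DataFrame(rows))


def simulate_subject(
    config: SimulationConfig, seed: int, subject_id: str = "sim"
) -> SimulatedSubject:
    """Draw one subject from the semi-Markov generative process.

    States follow the zero-diagonal transition chain with discretised Gamma
    sojourns; steps and HR are NB draws per state; the subject's resting-HR
    offset shifts every HR value; non-wear gaps (Poisson count per day,
    geometric length) are stamped as HR = 0.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    T = config.days * config.minutes_per_day
    pmfs = [sojourn_pmf(s) for s in config.sojourn]
    states = np.empty(T, dtype=np.int64)
    t = 0
    k = int(rng.choice(config.K, p=config.init_probs))
    while t < T:
        d = int(rng.choice(len(pmfs[k]), p=pmfs[k])) + 1
        states[t : t + d] = k
        t += d
        if t < T:
            k = int(rng.choice(config.K, p=config.trans[k]))
    steps = np.empty(T, dtype=np.int64)
    hr = np.empty(T, dtype=float)
    for k in range(config.K):
        mask = states == k
        n_k = int(mask.sum())
        if n_k:
            steps[mask] = _nb_draw(rng, config.step_params[k], n_k)
            hr[mask] = _nb_draw(rng, config.hr_params[k], n_k)
    hr = np.maximum(1.0, hr + config.resting_hr_offset)
    ranks = _label_order(config)
    labels = ranks[states]
    grid = _minute_grid(config)
    events = _events_from_labels(subject_id, grid, labels)

    # non-wear gaps: the device-like stream records HR = 0 there
    gap_p = 1.0 / max(1.0, config.nonwear_gap_mean_minutes)
    for day in range(config.days):
        n_gaps = rng.poisson(config.nonwear_gap_rate)
        for _ in range(n_gaps):
            start = day * config.minutes_per_day + int(
                rng.integers(0, config.minutes_per_day)
            )
            length = int(rng.geometric(gap_p))
            hr[start : min(T, start + length)] = 0.0

    minutes = MinuteSeries(
        subject_id,
        pd.DataFrame({"steps": steps, "heart_rate": hr, "worn": True}, index=grid),
    )
    return SimulatedSubject(
        subject_id=subject_id,
        true_states=states + 1,
        true_labels=labels,
        minutes=minutes,
        events=events,
        config=config,
        seed=seed,
    )


def inject_spurious_steps(
    subject: SimulatedSubject, prob: float, burst: NbParams, seed: int
) -> SimulatedSubject:
    """Contaminate sedentary minutes with step bursts, leaving HR untouched.

    Each true-sedentary minute independently receives an additional NB draw
    of steps with probability ``prob``; heart rate, true labels and the
    referent events are unchanged (the artefact is wrist movement, not
    activity).
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError("prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sed = subject.true_labels == int(ActivityLabel.SEDENTARY)
    hit = sed & (rng.random(len(sed)) < prob)
    data = subject.minutes.data.copy()
    extra = _nb_draw(rng, burst, int(hit.sum()))
    steps = data["steps"].to_numpy().copy()
    steps[hit] += extra
    data["steps"] = steps
    return SimulatedSubject(
        subject_id=subject.subject_id,
        true_states=subject.true_states,
        true_labels=subject.true_labels,
        minutes=MinuteSeries(subject.subject_id, data),
        events=subject.events,
        config=subject.config,
        seed=subject.seed,
    )


def generate_cohort(
    config: SimulationConfig,
    n_train: int,
    n_test: int,
    hr_offset_spread: float = 10.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[SimulatedSubject], list[SimulatedSubject]]:
    """Draw a training and a test cohort of independent subjects.

    Per-subject resting-HR offsets are uniform on +/- ``hr_offset_spread``
    bpm; per-subject seeds derive from the master seed.  When
    ``config.spurious_prob > 0`` every subject's sedentary minutes are
    contaminated accordingly.  With ``out_dir`` set, each subject's minute
    and events CSVs are written to ``out_dir/<subject_id>/``.
    """
    if n_train < 1:
        raise ValueError("need at least one training subject")
    rng = np.random.default_rng(seed)
    sub_seeds = np.random.SeedSequence(seed).generate_state(2 * (n_train + n_test)) % (2**31)
    cohorts: list[list[SimulatedSubject]] = []
    idx = 0
    for group, n in (("train", n_train), ("test", n_test)):
        subjects = []
        for i in range(n):
            offset = float(rng.uniform(-hr_offset_spread, hr_offset_spread))
            cfg = replace(config, resting_hr_offset=offset)
            sid = f"{group}{i + 1:02d}"
            subj = simulate_subject(cfg, seed=int(sub_seeds[idx]), subject_id=sid)
            idx += 1
            if config.spurious_prob > 0:
                subj = inject_spurious_steps(
                    subj, config.spurious_prob, config.spurious_steps,
                    seed=int(sub_seeds[idx]),
                )
            idx += 1
            subjects.append(subj)
        cohorts.append(subjects)
    train, test = cohorts
    if out_dir is not None:
        out = Path(out_dir)
        for subj in train + test:
            d = out / subj.subject_id
            d.mkdir(parents=True, exist_ok=True)
            write_minute_csv(subj.minutes, d / "minutes.csv")
            write_events_csv(subj.events, d / "events.csv")
    return train, test
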