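"""Sedentary-behaviour summary metrics.

Two headline metrics: the proportion of (worn, awake) time spent sedentary,
and the usual bout duration (UBD) — the bout length above and below which
half of all sedentary time is accrued, i.e. the duration-weighted median of
the bout durations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .ensemble import ActivityLabel, LabeledPrediction
from .errors import InsufficientDataError
from .io import EventSeries, PostureMinutes

_MINUTE_NS = 60_000_000_000


@dataclass
class BoutList:
    """Bout durations in minutes (from minute labels or posture events)."""

    durations: np.ndarray
    source: str  # "minute_labels" | "events"

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if (self.durations <= 0).any():
            raise ValueError("bout durations must be positive")

    def __len__(self) -> int:
        return len(self.durations)


def extract_bouts(
    data: Union[LabeledPrediction, EventSeries],
    target_label: ActivityLabel | str = ActivityLabel.SEDENTARY,
) -> BoutList:
    """Maximal runs of the target label (minutes) or matching events.

    For minute-label input, a bout is a maximal run of consecutive minutes
    carrying the target label; any timestamp gap (non-wear) terminates the
    bout.  For events input, each event of the target activity code is one
    bout, converted to minutes.
    """
    if isinstance(data, EventSeries):
        code = target_label if isinstance(target_label, str) else "sitting"
        durs = data.events.loc[data.events["activity"] == code, "duration_s"].to_numpy()
        return BoutList(durs / 60.0, source="events")
    is_target = data.labels == int(target_label)
    if len(is_target) == 0 or not is_target.any():
        return BoutList(np.empty(0), source="minute_labels")
    ts = data.timestamps.asi8
    contiguous = np.diff(ts) == _MINUTE_NS
    # a bout break occurs where the label changes or the grid has a gap
    breaks = np.flatnonzero((is_target[1:] != is_target[:-1]) | ~contiguous) + 1
    bounds = np.concatenate([[0], breaks, [len(is_target)]])
    durs = [
        float(e - s) for s, e in zip(bounds[:-1], bounds[1:]) if is_target[s]
    ]
    return BoutList(np.asarray(durs), source="minute_labels")


def proportion_sedentary(data: Union[LabeledPrediction, PostureMinutes]) -> float:
    """Fraction of worn time spent sedentary.

    Minute labels: sedentary minutes over all worn minutes.  Posture
    referent: sitting seconds over all recorded seconds.
    """
    if isinstance(data, PostureMinutes):
        total = float(data.recorded_s.sum())
        if total <= 0:
            raise InsufficientDataError("no recorded posture time")
        return float(data.data["sitting_s"].sum()) / total
    if len(data) == 0:
        raise InsufficientDataError("no worn minutes")
    return float(np.mean(data.labels == int(ActivityLabel.SEDENTARY)))


def usual_bout_duration(bouts: BoutList, interpolate: bool = False) -> float:
    """Duration-weighted median bout length (minutes).

    Sort bouts ascending and accumulate their durations; the UBD is the
    duration of the first bout at which the cumulative time reaches half the
    total.  With ``interpolate=True`` the cumulative-time curve is linearly
    interpolated at exactly half.
    """
    if len(bouts) == 0:
        raise InsufficientDataError("no bouts")
    d = np.sort(bouts.durations)
    cum = np.cumsum(d)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half))
    if not interpolate:
        return float(d[i])
    if i == 0:
        return float(d[0])
    c0, c1 = cum[i - 1], cum[i]
    if c1 == c0:
        return float(d[i])
    frac = (half - c0) / (c1 - c0)
    return float(d[i - 1] + frac * (d[i] - d[i - 1]))
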