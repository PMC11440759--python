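"""Reading, filtering and aligning minute-level wearable data and posture events.

Wrist wearables export step counts and heart rate on a one-minute grid
(Fitabase-style CSV); thigh-worn posture loggers export an events file with the
start time and duration of each sitting / standing / stepping bout
(activPAL-events-style CSV).  This module parses both, applies the wear-time
rules (zero/absent heart rate means the device was off; midnight-5AM is
excluded as unrepresentative), apportions events onto the minute grid, and
intersects the two devices' worn minutes so that agreement statistics compare
like with like.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

ACTIVITY_CODES = ("sitting", "standing", "stepping")

#: default column names for minute-level CSV exports
MINUTE_COLUMNS = {"time": "time", "steps": "steps", "heart_rate": "heart_rate"}
#: default column names for posture events CSV exports
EVENT_COLUMNS = {"start": "start", "duration_s": "duration_s", "activity": "activity"}


@dataclass
class MinuteSeries:
    """Per-subject minute grid of step counts and heart rate with wear flags.

    ``data`` is indexed by timezone-naive minute timestamps (strictly
    increasing, each on an exact minute boundary) with columns ``steps``
    (non-negative int), ``heart_rate`` (bpm, NaN if missing) and ``worn``
    (bool).
    """

    subject_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.data.index)
        if len(idx) and not idx.is_monotonic_increasing:
            self.data = self.data.sort_index()
            idx = pd.DatetimeIndex(self.data.index)
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise IntegrityError(f"duplicate minute {dup} for subject {self.subject_id}")
        if len(idx) and ((idx.second != 0) | (idx.microsecond != 0)).any():
            raise FormatError("timestamps must fall on exact minute boundaries")
        steps = self.data["steps"].to_numpy()
        finite = np.isfinite(steps)
        if (steps[finite] < 0).any():
            raise IntegrityError("negative step counts")
        if not np.allclose(steps[finite], np.round(steps[finite])):
            raise IntegrityError("non-integral step counts")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.index)

    @property
    def steps(self) -> np.ndarray:
        return self.data["steps"].to_numpy()

    @property
    def heart_rate(self) -> np.ndarray:
        return self.data["heart_rate"].to_numpy(dtype=float)

    @property
    def worn(self) -> np.ndarray:
        return self.data["worn"].to_numpy(dtype=bool)


@dataclass
class EventSeries:
    """Ordered, non-overlapping posture events (start, duration in s, activity)."""

    subject_id: str
    events: pd.DataFrame  # columns: start (datetime64), duration_s (float), activity

    def __post_init__(self) -> None:
        ev = self.events.sort_values("start", kind="stable").reset_index(drop=True)
        if (ev["duration_s"] <= 0).any():
            raise IntegrityError("event durations must be positive")
        bad = ~ev["activity"].isin(ACTIVITY_CODES)
        if bad.any():
            raise FormatError(f"unknown activity code(s): {sorted(ev.loc[bad, 'activity'].unique())}")
        ends = ev["start"] + pd.to_timedelta(ev["duration_s"], unit="s")
        if len(ev) > 1 and (ev["start"].iloc[1:].to_numpy() < ends.iloc[:-1].to_numpy()).any():
            i = int(np.argmax(ev["start"].iloc[1:].to_numpy() < ends.iloc[:-1].to_numpy()))
            raise IntegrityError(f"overlapping events at index {i}")
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class PostureMinutes:
    """Seconds of sitting / standing / stepping per minute of a minute grid.

    Per minute the three columns each lie in [0, 60] and sum to at most 60;
    any shortfall is time the posture logger was not recording.
    """

    subject_id: str
    data: pd.DataFrame  # index: minute timestamps; columns sitting_s, standing_s, stepping_s

    def __post_init__(self) -> None:
        cols = self.data[["sitting_s", "standing_s", "stepping_s"]]
        if (cols.to_numpy() < -1e-9).any():
            raise IntegrityError("negative per-minute activity seconds")
        if (cols.sum(axis=1).to_numpy() > 60 + 1e-6).any():
            raise IntegrityError("per-minute activity seconds exceed 60")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.index)

    @property
    def recorded_s(self) -> np.ndarray:
        return self.data[["sitting_s", "standing_s", "stepping_s"]].sum(axis=1).to_numpy()


@dataclass
class MatchedSeries:
    """Minutes present and worn on both devices, with both payloads aligned."""

    subject_id: str
    data: pd.DataFrame  # columns: steps, heart_rate, sitting_s, standing_s, stepping_s

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.index)


def _parse_times(raw: pd.Series, what: str) -> pd.DatetimeIndex:
    try:
        times = pd.to_datetime(raw, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable {what} timestamp: {exc}") from exc
    return pd.DatetimeIndex(times)


def read_minute_series(
    path,
    column_map: Mapping[str, str] | None = None,
    subject_id: str | None = None,
) -> MinuteSeries:
    """Read a Fitabase-style minute-level CSV into a :class:`MinuteSeries`.

    ``column_map`` maps the logical names ``time``, ``steps`` and
    ``heart_rate`` to the CSV's column names.  Missing minutes are left absent
    (never imputed); duplicated minutes raise :class:`IntegrityError`.
    """
    cols = {**MINUTE_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path)
    for key in ("time", "steps", "heart_rate"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing column {cols[key]!r} in {path}")
    times = _parse_times(df[cols["time"]], "minute")
    steps = pd.to_numeric(df[cols["steps"]], errors="raise")
    hr = pd.to_numeric(df[cols["heart_rate"]], errors="coerce")
    out = pd.DataFrame(
        {"steps": steps.to_numpy(), "heart_rate": hr.to_numpy(dtype=float), "worn": True},
        index=times,
    )
    sid = subject_id if subject_id is not None else str(getattr(path, "stem", path))
    return MinuteSeries(sid, out)


def read_events(
    path,
    column_map: Mapping[str, str] | None = None,
    subject_id: str | None = None,
) -> EventSeries:
    """Read an activPAL-events-style CSV into an :class:`EventSeries`.

    Activity codes are lower-cased and must normalise into
    ``{sitting, standing, stepping}``; events are returned sorted by start.
    """
    cols = {**EVENT_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path)
    for key in ("start", "duration_s", "activity"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing column {cols[key]!r} in {path}")
    ev = pd.DataFrame(
        {
            "start": _parse_times(df[cols["start"]], "event start"),
            "duration_s": pd.to_numeric(df[cols["duration_s"]], errors="raise").astype(float),
            "activity": df[cols["activity"]].astype(str).str.strip().str.lower(),
        }
    )
    sid = subject_id if subject_id is not None else str(getattr(path, "stem", path))
    return EventSeries(sid, ev)


def filter_wear(
    series: MinuteSeries,
    night_start: dt.time = dt.time(0, 0),
    night_end: dt.time = dt.time(5, 0),
) -> MinuteSeries:
    """Drop non-wear and night minutes.

    A minute with zero or missing heart rate is treated as non-wear and
    removed.  Minutes whose clock time falls in the half-open window
    ``[night_start, night_end)`` are removed regardless of wear.  Idempotent.
    """
    df = series.data
    hr = df["heart_rate"].to_numpy(dtype=float)
    worn = np.isfinite(hr) & (hr > 0)
    clock = pd.DatetimeIndex(df.index).time
    if night_start <= night_end:
        at_night = (clock >= night_start) & (clock < night_end)
    else:  # window wrapping midnight
        at_night = (clock >= night_start) | (clock < night_end)
    keep = worn & ~at_night
    out = df.loc[keep].copy()
    out["worn"] = True
    return MinuteSeries(series.subject_id, out)


def select_valid_days(
    posture: PostureMinutes,
    steps_per_day: Mapping[dt.date, float] | pd.Series,
    min_wear_minutes: int = 600,
    min_steps: float = 500.0,
    max_single_activity_frac: float = 0.95,
) -> set[dt.date]:
    """Calendar days meeting the valid-day criteria.

    A day is valid when it has >= ``min_wear_minutes`` worn awake minutes,
    >= ``min_steps`` steps, and less than ``max_single_activity_frac`` of its
    worn time in any one activity class.
    """
    if isinstance(steps_per_day, pd.Series):
        steps_per_day = {
            (k.date() if hasattr(k, "date") else k): v for k, v in steps_per_day.items()
        }
    df = posture.data
    day = pd.DatetimeIndex(df.index).normalize()
    per_class = df[["sitting_s", "standing_s", "stepping_s"]]
    recorded = per_class.sum(axis=1)
    valid: set[dt.date] = set()
    for d, grp in per_class.groupby(day):
        rec = recorded.loc[grp.index]
        worn_minutes = int((rec > 0).sum())
        total_s = float(rec.sum())
        date = d.date()
        if worn_minutes < min_wear_minutes or total_s <= 0:
            continue
        if float(steps_per_day.get(date, 0.0)) < min_steps:
            continue
        fracs = grp.sum(axis=0).to_numpy() / total_s
        if (fracs >= max_single_activity_frac).any():
            continue
        valid.add(date)
    return valid


def events_to_minutes(events: EventSeries, grid: pd.DatetimeIndex) -> PostureMinutes:
    """Apportion event durations onto a minute grid by exact overlap length.

    Minute stamp ``t`` covers ``[t, t + 60 s)``; an event contributes to every
    minute it overlaps, in proportion to the overlap.  Total seconds per
    activity are conserved up to the part of each event outside the grid.
    """
    grid = pd.DatetimeIndex(grid).sort_values()
    out = pd.DataFrame(
        0.0, index=grid, columns=["sitting_s", "standing_s", "stepping_s"]
    )
    if len(grid) == 0 or len(events) == 0:
        return PostureMinutes(events.subject_id, out)
    grid_ns = grid.asi8  # minute starts, ns since epoch
    pos = {int(t): i for i, t in enumerate(grid_ns)}
    minute_ns = 60_000_000_000
    col = {"sitting": "sitting_s", "standing": "standing_s", "stepping": "stepping_s"}
    arr = out.to_numpy()
    ci = {"sitting_s": 0, "standing_s": 1, "stepping_s": 2}
    for start, dur, act in events.events.itertuples(index=False):
        s = int(pd.Timestamp(start).value)
        e = s + int(round(dur * 1e9))
        first = (s // minute_ns) * minute_ns
        m = first
        while m < e:
            ov = (min(e, m + minute_ns) - max(s, m)) / 1e9
            i = pos.get(m)
            if i is not None and ov > 0:
                arr[i, ci[col[act]]] += ov
            m += minute_ns
    out.loc[:, :] = arr
    return PostureMinutes(events.subject_id, out)


def match_minutes(
    device: MinuteSeries,
    posture: PostureMinutes,
    posture_offset_minutes: int = 0,
) -> MatchedSeries:
    """Intersect device and posture minutes after an optional posture shift.

    ``posture_offset_minutes`` shifts the posture timestamps (e.g. -60 to undo
    a daylight-saving hour on the logger's clock) before intersecting.  Only
    minutes worn on both devices (device ``worn`` flag; posture recorded > 0 s)
    are retained.
    """
    p = posture.data.copy()
    if posture_offset_minutes:
        p.index = p.index + pd.Timedelta(minutes=posture_offset_minutes)
    p = p.loc[p.sum(axis=1) > 0]
    d = device.data.loc[device.data["worn"]]
    common = d.index.intersection(p.index)
    if len(common) == 0:
        warnings.warn(
            f"no overlapping worn minutes for subject {device.subject_id}",
            stacklevel=2,
        )
    merged = d.loc[common, ["steps", "heart_rate"]].join(p.loc[common])
    return MatchedSeries(device.subject_id, merged)


def write_minute_csv(series: MinuteSeries, path) -> None:
    out = series.data.reset_index(names="time")[["time", "steps", "heart_rate"]]
    out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, lineterminator="\r\n")


def write_events_csv(events: EventSeries, path) -> None:
    out = events.events.copy()
    out["start"] = out["start"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str.slice(0, 21)
    out.to_csv(path, index=False, lineterminator="\r\n")
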