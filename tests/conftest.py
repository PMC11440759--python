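from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stephen.io import MinuteSeries
from stephen.simulate import SimulationConfig, simulate_subject

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_minutes(
    steps,
    hr=None,
    start: str = "2024-01-01 08:00",
    subject_id: str = "s1",
    gaps_after: tuple[int, ...] = (),
) -> MinuteSeries:
    """MinuteSeries from plain arrays, optionally with grid gaps.

    ``gaps_after=(i,)`` shifts every timestamp after position i by an extra
    5 minutes, creating a non-wear hole in the grid.
    """
    n = len(steps)
    offsets = np.zeros(n, dtype=np.int64)
    for g in gaps_after:
        offsets[g + 1 :] += 5
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) + offsets, unit="min")
    hr = np.full(n, 70.0) if hr is None else np.asarray(hr, dtype=float)
    df = pd.DataFrame(
        {"steps": np.asarray(steps), "heart_rate": hr, "worn": True}, index=ts
    )
    return MinuteSeries(subject_id, df)


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Default well-separated 4-state cohort parameters, no gaps."""
    return SimulationConfig(days=3, minutes_per_day=960, nonwear_gap_rate=0.0)


@pytest.fixture(scope="session")
def clean_subject(clean_config):
    """One uncontaminated subject at T = 2880 minutes."""
    return simulate_subject(clean_config, seed=42, subject_id="clean42")
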