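"""Shared fixtures: small synthetic cohorts and helpers for the test suite."""

from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from chronoperf.records import PvtResponse, Schedule, SleepSession, TaskSession
from chronoperf.simulate import SimConfig, simulate_cohort


def small_config(**overrides) -> SimConfig:
    base = dict(n_regular=2, n_shift=1, n_student=1, days=21)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """Full cohort at study scale under the packaged defaults."""
    return simulate_cohort(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(), seed=7)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    small_cohort.to_files(d)
    return d


def make_task(pid: str, ts: datetime, rts, naa: int = 15, false_starts=()) -> TaskSession:
    responses = [PvtResponse(float(rt), False) for rt in rts]
    responses += [PvtResponse(float(rt), True) for rt in false_starts]
    return TaskSession(participant_id=pid, timestamp=ts, pvt_responses=responses, add_attempts=naa)


def make_tasks_from_mrts(pid: str, mrts, naas=None, start=datetime(2019, 3, 5, 9, 0)):
    """One single-response task per MRT, 3 h apart (first is the first instance)."""
    naas = naas or [15] * len(mrts)
    return [
        make_task(pid, start + timedelta(hours=3 * i), [mrt], naa)
        for i, (mrt, naa) in enumerate(zip(mrts, naas))
    ]


def make_night(pid: str, start: datetime, duration_min: float, stages: bool = True) -> SleepSession:
    end = start + timedelta(minutes=duration_min)
    stage_minutes = None
    if stages and duration_min > 180:
        stage_minutes = {
            "rem": round(0.18 * duration_min, 1),
            "light": round(0.53 * duration_min, 1),
            "deep": round(0.16 * duration_min, 1),
            "awake": round(0.13 * duration_min, 1),
        }
    return SleepSession(pid, start, end, stage_minutes=stage_minutes)


def week_schedule(pid: str, first_monday: date, weeks: int = 3) -> Schedule:
    """Mon-Fri work, weekend free, starting at a Monday."""
    labels = {}
    for k in range(weeks * 7 + 1):
        d = first_monday + timedelta(days=k)
        labels[d] = "work" if d.weekday() < 5 else "free"
    return Schedule(pid, labels)


def rolling_window_means(stream, tasks, channel: str, window: int) -> np.ndarray:
    """Window means at task minutes via a rolling mean (test-side shortcut)."""
    roll = stream.frame[channel].rolling(window, min_periods=window // 2).mean()
    out = []
    for t in tasks:
        key = pd.Timestamp(t.timestamp).floor("min")
        out.append(roll.get(key, np.nan))
    return np.asarray(out, dtype=float)
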