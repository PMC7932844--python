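"""Core record types for the in-the-wild cognitive-performance study design.

Four kinds of on-disk records feed the analysis:

* :class:`TaskSession` — one smartphone task battery: a Psychomotor Vigilance
  Test (PVT, a reaction-time probe of vigilant attention) followed by an
  Addition Test (ADD, a fixed-duration mental-arithmetic throughput probe),
  plus a Karolinska Sleepiness Scale rating and a caffeine flag (carried but
  not analysed).
* :class:`SleepSession` — one tracker-recorded sleep bout with stage minutes
  (REM / light / deep / awake), reported only for bouts longer than 3 hours.
* :class:`MinuteStream` — minute-resolution heart-rate and activity channels
  plus a per-day resting heart rate.
* :class:`Schedule` — per-calendar-date work/free labels, needed for the
  chronotype (mid-sleep on free days) computation.

All timestamps are naive local time at minute resolution; daylight-saving
transitions are not modelled, matching consumer-tracker exports. A sleep
session "belongs" to the calendar date it ends on (its wake date).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import NamedTuple

import numpy as np
import pandas as pd

STAGES = ("rem", "light", "deep", "awake")
#: Stage breakdown is only reported for sessions longer than this (minutes).
STAGE_MIN_ELAPSED = 180.0
CHANNELS = ("heart_rate", "calories", "steps", "distance", "floors")

HR_MIN, HR_MAX = 25.0, 250.0


class RecordValidationError(ValueError):
    """A record violates one of its structural invariants."""


class PvtResponse(NamedTuple):
    """One PVT stimulus response: reaction time in ms and a false-start flag."""

    response_time_ms: float
    false_start: bool = False


def clock_hours(ts: datetime) -> float:
    """Clock time of ``ts`` as fractional hours in [0, 24)."""
    return ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9


@dataclass(order=True)
class TaskSession:
    """One completed PVT + ADD battery.

    ``add_attempts`` is the number of additions attempted (NAA). Instances
    order by (participant, timestamp) so a sorted list is analysis-ready.
    """

    participant_id: str
    timestamp: datetime
    pvt_responses: list[PvtResponse] = field(default_factory=list, compare=False)
    add_attempts: int = 0
    kss: int | None = field(default=None, compare=False)
    caffeine_last_hour: bool | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.pvt_responses = [PvtResponse(float(rt), bool(fs)) for rt, fs in self.pvt_responses]
        for r in self.pvt_responses:
            if not r.false_start and not r.response_time_ms > 0:
                raise RecordValidationError(
                    f"non-false-start response time must be positive, got {r.response_time_ms}"
                )
        if self.add_attempts < 0:
            raise RecordValidationError(f"add_attempts must be >= 0, got {self.add_attempts}")
        if self.kss is not None and not 1 <= int(self.kss) <= 9:
            raise RecordValidationError(f"kss must be in 1..9, got {self.kss}")


@dataclass
class SleepSession:
    """One tracker-recorded sleep bout.

    ``stage_minutes`` maps rem/light/deep/awake to minutes; it may be absent,
    and is only *usable* for staging analyses when the bout exceeds 3 hours
    (:attr:`has_stages`). Durations are total elapsed time in bed, the same
    denominator the stage percentages use.
    """

    participant_id: str
    start: datetime
    end: datetime
    minutes_asleep: float | None = None
    stage_minutes: dict[str, float] | None = None
    efficiency: float | None = None
    awakenings_gt5min: int | None = None
    onset_latency: float | None = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise RecordValidationError(
                f"sleep session must end after it starts ({self.start} .. {self.end})"
            )
        if self.stage_minutes is not None:
            unknown = set(self.stage_minutes) - set(STAGES)
            if unknown:
                raise RecordValidationError(f"unknown sleep stages: {sorted(unknown)}")
            total = sum(self.stage_minutes.values())
            if total > self.elapsed_minutes + 1e-6:
                raise RecordValidationError(
                    f"stage minutes sum to {total:.1f} > elapsed {self.elapsed_minutes:.1f}"
                )
            if any(v < 0 for v in self.stage_minutes.values()):
                raise RecordValidationError("stage minutes must be nonnegative")
        if self.minutes_asleep is not None and self.minutes_asleep > self.elapsed_minutes + 1e-6:
            raise RecordValidationError("minutes_asleep exceeds elapsed time")
        if self.efficiency is not None and not 0 <= self.efficiency <= 100:
            raise RecordValidationError(f"efficiency must be in [0, 100], got {self.efficiency}")

    @property
    def elapsed_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    # Total session duration: the quantity entering sleep need / debt and the
    # stage-percentage denominator.
    @property
    def duration_minutes(self) -> float:
        return self.elapsed_minutes

    @property
    def wake_date(self) -> date:
        """Calendar date the session belongs to: the date of waking."""
        return self.end.date()

    @property
    def mid_sleep(self) -> datetime:
        return self.start + (self.end - self.start) / 2

    @property
    def mid_sleep_hours(self) -> float:
        """Mid-sleep point as clock hours in [0, 24)."""
        return clock_hours(self.mid_sleep)

    @property
    def sleep_end_hours(self) -> float:
        return clock_hours(self.end)

    @property
    def has_stages(self) -> bool:
        """Stage breakdown present *and* usable (session longer than 3 h)."""
        return self.stage_minutes is not None and self.elapsed_minutes > STAGE_MIN_ELAPSED


class MinuteStream:
    """Minute-resolution physiology for one participant.

    Wraps a DataFrame indexed by minute timestamps with columns from
    ``heart_rate, calories, steps, distance, floors`` (any subset), plus a
    per-day resting heart rate map. Duplicate minutes collapse to the
    last-written value with a warning.
    """

    def __init__(
        self,
        participant_id: str,
        frame: pd.DataFrame | None = None,
        resting_hr: dict[date, float] | None = None,
    ) -> None:
        self.participant_id = participant_id
        self.resting_hr = dict(resting_hr or {})
        if frame is None:
            frame = pd.DataFrame(columns=list(CHANNELS), index=pd.DatetimeIndex([], name="timestamp"))
        if not isinstance(frame.index, pd.DatetimeIndex):
            raise RecordValidationError("minute stream frame must have a DatetimeIndex")
        frame = frame.sort_index()
        frame.index = frame.index.floor("min")
        if frame.index.has_duplicates:
            ndup = int(frame.index.duplicated(keep="last").sum())
            warnings.warn(
                f"{participant_id}: {ndup} duplicate minute(s) collapsed to last-written value",
                stacklevel=2,
            )
            frame = frame[~frame.index.duplicated(keep="last")]
        unknown = set(frame.columns) - set(CHANNELS)
        if unknown:
            raise RecordValidationError(f"unknown stream channels: {sorted(unknown)}")
        if "heart_rate" in frame.columns:
            hr = frame["heart_rate"].dropna()
            bad = hr[(hr < HR_MIN) | (hr > HR_MAX)]
            if len(bad):
                raise RecordValidationError(
                    f"heart_rate outside [{HR_MIN:g}, {HR_MAX:g}] at {bad.index[0]}"
                )
        for ch in ("calories", "steps", "distance", "floors"):
            if ch in frame.columns:
                vals = frame[ch].dropna()
                if (vals < 0).any():
                    raise RecordValidationError(f"{ch} must be nonnegative")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MinuteStream):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.frame.equals(other.frame)
            and self.resting_hr == other.resting_hr
        )

    def value_at(self, ts: datetime, channel: str) -> float | None:
        """Channel value at the minute containing ``ts``, or None."""
        key = pd.Timestamp(ts).floor("min")
        if channel in self.frame.columns and key in self.frame.index:
            v = self.frame.at[key, channel]
            if pd.notna(v):
                return float(v)
        return None


@dataclass
class Schedule:
    """Work/free labels per calendar date for one participant."""

    participant_id: str
    labels: dict[date, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values() if v not in ("work", "free")}
        if bad:
            raise RecordValidationError(f"schedule labels must be 'work' or 'free', got {sorted(bad)}")

    def label(self, d: date) -> str:
        try:
            return self.labels[d]
        except KeyError:
            raise KeyError(f"{self.participant_id}: date {d} not in schedule") from None

    def is_free(self, d: date) -> bool:
        return self.label(d) == "free"

    @property
    def span(self) -> tuple[date, date]:
        ds = sorted(self.labels)
        return ds[0], ds[-1]

    def covers(self, dates) -> bool:
        return all(d in self.labels for d in dates)


def minutes_between(a: datetime, b: datetime) -> float:
    """Signed minutes from ``b`` to ``a`` (positive when a is later)."""
    return (a - b).total_seconds() / 60.0


def hours_to_hhmm(hours: float) -> str:
    """Render fractional clock hours as an hh:mm string, flooring to the minute."""
    total = int(np.floor(hours * 60.0 + 1e-9)) % (24 * 60)
    h, m = divmod(total, 60)
    return f"{h:02d}:{m:02d}"


def combine_clock(d: date, hours: float) -> datetime:
    """Datetime at clock time ``hours`` on date ``d``."""
    return datetime(d.year, d.month, d.day) + timedelta(hours=hours % 24.0)
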