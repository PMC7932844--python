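"""Task-time physiological features from minute streams.

For each task we extract the current heart rate (the stream value at the
task minute, else the nearest minute within a small tolerance), the day's
resting heart rate, and — for each channel in heart rate, calories,
distance, steps and each lookback window of 10 and 60 minutes — the window
mean and variance.

Window convention: the half-open interval (t - w, t] of minute slots,
including the task minute. Variance is the population variance (ddof=0) by
default. A window's statistics are reported only when at least half of its
minutes carry data (configurable coverage threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .records import MinuteStream, TaskSession

WINDOW_CHANNELS = ("heart_rate", "calories", "distance", "steps")
DEFAULT_WINDOWS = (10, 60)
MIN_COVERAGE = 0.5
CURRENT_HR_TOLERANCE_MIN = 5


def window_stats(
    stream: MinuteStream,
    t: datetime,
    window: int,
    channel: str,
    min_coverage: float = MIN_COVERAGE,
    ddof: int = 0,
) -> tuple[float | None, float | None, float]:
    """(mean, variance, coverage) of a channel over the last ``window`` minutes.

    Mean and variance are None when the fraction of minutes with data falls
    below ``min_coverage``.
    """
    if window <= 0:
        raise ValueError("window must be a positive number of minutes")
    end = pd.Timestamp(t).floor("min")
    start = end - pd.Timedelta(minutes=window)
    if channel not in stream.frame.columns:
        return None, None, 0.0
    sel = stream.frame.loc[(stream.frame.index > start) & (stream.frame.index <= end), channel].dropna()
    coverage = len(sel) / window
    if coverage < min_coverage or len(sel) == 0:
        return None, None, coverage
    vals = sel.to_numpy(dtype=float)
    var = float(vals.var(ddof=ddof)) if len(vals) > ddof else 0.0
    return float(vals.mean()), var, coverage


def current_heart_rate(
    stream: MinuteStream, t: datetime, tolerance_min: int = CURRENT_HR_TOLERANCE_MIN
) -> float | None:
    """Heart rate at the task minute, else the nearest within the tolerance."""
    if "heart_rate" not in stream.frame.columns:
        return None
    exact = stream.value_at(t, "heart_rate")
    if exact is not None:
        return exact
    hr = stream.frame["heart_rate"].dropna()
    if hr.empty:
        return None
    key = pd.Timestamp(t).floor("min")
    deltas = (hr.index - key).to_numpy()
    i = int(np.argmin(np.abs(deltas)))
    if abs(deltas[i]) <= np.timedelta64(tolerance_min, "m"):
        return float(hr.iloc[i])
    return None


@dataclass
class MomentaryFeatures:
    """Physiological context of one task battery."""

    participant_id: str
    timestamp: datetime
    current_hr: float | None
    resting_hr: float | None
    #: keys like "heart_rate_mean_60", "steps_var_10"
    window_values: dict[str, float | None] = field(default_factory=dict)
    coverage: dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "timestamp": self.timestamp,
            "current_hr": self.current_hr,
            "resting_hr": self.resting_hr,
        }
        d.update(self.window_values)
        return d


def momentary_feature_vector(
    task: TaskSession,
    stream: MinuteStream,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    min_coverage: float = MIN_COVERAGE,
    ddof: int = 0,
) -> MomentaryFeatures:
    """All task-time features for one battery; missing values stay None."""
    window_values: dict[str, float | None] = {}
    coverage: dict[int, float] = {}
    for w in windows:
        for ch in WINDOW_CHANNELS:
            mean, var, cov = window_stats(stream, task.timestamp, w, ch, min_coverage, ddof)
            window_values[f"{ch}_mean_{w}"] = mean
            window_values[f"{ch}_var_{w}"] = var
            coverage[w] = cov
    return MomentaryFeatures(
        participant_id=task.participant_id,
        timestamp=task.timestamp,
        current_hr=current_heart_rate(stream, task.timestamp),
        resting_hr=stream.resting_hr.get(task.timestamp.date()),
        window_values=window_values,
        coverage=coverage,
    )


def features_frame(feats: list[MomentaryFeatures]) -> pd.DataFrame:
    """Momentary features as a DataFrame (one row per task)."""
    return pd.DataFrame([f.as_dict() for f in feats])
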