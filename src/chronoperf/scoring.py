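"""Session and daily scoring of PVT alertness and ADD cognitive throughput.

Each task battery yields a session median response time MRT (ms, over
non-false-start stimuli) and a number of additions attempted NAA. Scores are
expressed relative to the participant's own baseline:

    RRT = (1 - MRT / mean_MRT) * 100        (higher = more alert)
    RAA = (NAA / mean_NAA - 1) * 100        (higher = more throughput)

where the baselines are participant means over *retained* sessions, so each
participant's mean RRT and RAA over retained sessions is identically zero.

Retention filters, in order:

1. drop each participant's chronologically first battery (app unfamiliarity);
2. PVT only: drop sessions with MRT missing or strictly above 800 ms;
3. drop sessions strictly more than 3 SDs from the participant's mean
   (computed over the survivors of the previous steps; population SD by
   default).

Participants contributing fewer than 42 completed batteries are excluded
from all downstream analyses (``include_participants``). Daily scores use
the per-day median of retained sessions with the across-days mean of daily
medians as baseline, mirroring the session-level definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime

import numpy as np
import pandas as pd

from .records import TaskSession

logger = logging.getLogger(__name__)

RT_THRESHOLD_MS = 800.0
SD_LIMIT = 3.0
MIN_TASKS = 42


@dataclass
class SessionScore:
    """Scores for one task battery; relative scores only when retained."""

    participant_id: str
    timestamp: datetime
    mrt: float | None
    rrt: float | None
    naa: int
    raa: float | None
    retained_pvt: bool
    retained_add: bool


def median_response_time(session: TaskSession) -> float | None:
    """Session median reaction time over non-false-start stimuli, or None."""
    rts = [r.response_time_ms for r in session.pvt_responses if not r.false_start]
    if not rts:
        return None
    return float(np.median(rts))


def _sd_mask(values: np.ndarray, candidate: np.ndarray, sd_limit: float, ddof: int) -> np.ndarray:
    """Keep entries of ``candidate`` within sd_limit SDs of candidate's mean.

    Entries where ``candidate`` is False stay dropped. Zero SD keeps all
    survivors (|x - mean| = 0 is never strictly outside).
    """
    keep = candidate.copy()
    vals = values[candidate]
    if len(vals) == 0:
        return keep
    mean = vals.mean()
    sd = vals.std(ddof=ddof) if len(vals) > ddof else 0.0
    keep[candidate] = np.abs(values[candidate] - mean) <= sd_limit * sd
    return keep


def _first_instance_mask(n: int) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    if n:
        mask[0] = False
    return mask


def filter_pvt_sessions(
    sessions: list[TaskSession],
    rt_threshold_ms: float = RT_THRESHOLD_MS,
    sd_limit: float = SD_LIMIT,
    ddof: int = 0,
) -> list[bool]:
    """Retention flags for the PVT score, applied per participant.

    Order: first-instance drop, then the absolute MRT threshold (strictly
    above drops; exactly at the threshold is retained), then the SD rule on
    the survivors.
    """
    flags = np.zeros(len(sessions), dtype=bool)
    frame = pd.DataFrame(
        {
            "pid": [s.participant_id for s in sessions],
            "mrt": [median_response_time(s) for s in sessions],
        }
    )
    for pid, grp in frame.groupby("pid", sort=False):
        idx = grp.index.to_numpy()
        mrt = grp["mrt"].to_numpy(dtype=float)
        keep = _first_instance_mask(len(idx))
        keep &= ~np.isnan(mrt)
        keep &= ~(mrt > rt_threshold_ms)
        keep = _sd_mask(mrt, keep, sd_limit, ddof)
        if not keep.any():
            logger.warning("participant %s: no PVT sessions survive filtering", pid)
        flags[idx] = keep
    return list(flags)


def filter_add_sessions(
    sessions: list[TaskSession], sd_limit: float = SD_LIMIT, ddof: int = 0
) -> list[bool]:
    """Retention flags for the ADD score: first-instance drop + SD rule only."""
    flags = np.zeros(len(sessions), dtype=bool)
    frame = pd.DataFrame(
        {
            "pid": [s.participant_id for s in sessions],
            "naa": [float(s.add_attempts) for s in sessions],
        }
    )
    for pid, grp in frame.groupby("pid", sort=False):
        idx = grp.index.to_numpy()
        naa = grp["naa"].to_numpy(dtype=float)
        keep = _first_instance_mask(len(idx))
        keep = _sd_mask(naa, keep, sd_limit, ddof)
        if not keep.any():
            logger.warning("participant %s: no ADD sessions survive filtering", pid)
        flags[idx] = keep
    return list(flags)


def relative_response_time(mrt: np.ndarray, retained: np.ndarray) -> np.ndarray:
    """RRT (%) for retained sessions of one participant; NaN elsewhere."""
    out = np.full(len(mrt), np.nan)
    if retained.any():
        baseline = mrt[retained].mean()
        out[retained] = (1.0 - mrt[retained] / baseline) * 100.0
    return out


def relative_additions(naa: np.ndarray, retained: np.ndarray) -> np.ndarray:
    """RAA (%) for retained sessions of one participant; NaN elsewhere."""
    out = np.full(len(naa), np.nan)
    if retained.any():
        baseline = naa[retained].mean()
        out[retained] = (naa[retained] / baseline - 1.0) * 100.0
    return out


def score_sessions(
    sessions: list[TaskSession],
    rt_threshold_ms: float = RT_THRESHOLD_MS,
    sd_limit: float = SD_LIMIT,
    ddof: int = 0,
) -> list[SessionScore]:
    """Score every battery, applying all retention filters.

    ``sessions`` must be time-sorted within each participant (the JSONL
    reader guarantees this).
    """
    ret_pvt = np.array(filter_pvt_sessions(sessions, rt_threshold_ms, sd_limit, ddof))
    ret_add = np.array(filter_add_sessions(sessions, sd_limit, ddof))
    mrt = np.array([np.nan if (m := median_response_time(s)) is None else m for s in sessions])
    naa = np.array([float(s.add_attempts) for s in sessions])
    pids = np.array([s.participant_id for s in sessions])
    rrt = np.full(len(sessions), np.nan)
    raa = np.full(len(sessions), np.nan)
    for pid in pd.unique(pids):
        m = pids == pid
        rrt[m] = relative_response_time(mrt[m], ret_pvt[m])
        raa[m] = relative_additions(naa[m], ret_add[m])
    return [
        SessionScore(
            participant_id=s.participant_id,
            timestamp=s.timestamp,
            mrt=None if np.isnan(mrt[i]) else float(mrt[i]),
            rrt=None if np.isnan(rrt[i]) else float(rrt[i]),
            naa=int(naa[i]),
            raa=None if np.isnan(raa[i]) else float(raa[i]),
            retained_pvt=bool(ret_pvt[i]),
            retained_add=bool(ret_add[i]),
        )
        for i, s in enumerate(sessions)
    ]


def scores_frame(scores: list[SessionScore]) -> pd.DataFrame:
    """Session scores as a DataFrame (one row per battery)."""
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in scores],
            "timestamp": [s.timestamp for s in scores],
            "mrt": [np.nan if s.mrt is None else s.mrt for s in scores],
            "rrt": [np.nan if s.rrt is None else s.rrt for s in scores],
            "naa": [s.naa for s in scores],
            "raa": [np.nan if s.raa is None else s.raa for s in scores],
            "retained_pvt": [s.retained_pvt for s in scores],
            "retained_add": [s.retained_add for s in scores],
        }
    )


def include_participants(sessions: list[TaskSession], min_tasks: int = MIN_TASKS) -> set[str]:
    """Participants with at least ``min_tasks`` completed batteries.

    Counts completed batteries before any session-level quality filter.
    Raises if nobody qualifies.
    """
    counts: dict[str, int] = {}
    for s in sessions:
        counts[s.participant_id] = counts.get(s.participant_id, 0) + 1
    kept = {pid for pid, n in counts.items() if n >= min_tasks}
    dropped = sorted(set(counts) - kept)
    if dropped:
        logger.info("excluding %d participant(s) with < %d tasks: %s", len(dropped), min_tasks, dropped)
    if not kept:
        raise ValueError(f"no participant completed at least {min_tasks} tasks")
    return kept


@dataclass
class DailyScore:
    """Per-day medians and relative daily scores for one participant-day."""

    participant_id: str
    date: date
    daily_median_mrt: float | None
    daily_median_naa: float | None
    relative_daily_rrt: float | None
    relative_daily_raa: float | None


def daily_relative_scores(scores: list[SessionScore]) -> pd.DataFrame:
    """Daily medians of retained MRT/NAA plus relative daily scores.

    A calendar day is local midnight-to-midnight. The relative daily score
    applies the RRT/RAA functional forms with the participant's across-days
    mean of daily medians as baseline, so each participant's mean relative
    daily score over their days is zero.
    """
    df = scores_frame(scores)
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    rows = []
    for pid, grp in df.groupby("participant_id", sort=True):
        med_mrt = grp[grp["retained_pvt"]].groupby("date")["mrt"].median()
        med_naa = grp[grp["retained_add"]].groupby("date")["naa"].median()
        base_mrt = med_mrt.mean() if len(med_mrt) else np.nan
        base_naa = med_naa.mean() if len(med_naa) else np.nan
        for d in sorted(set(med_mrt.index) | set(med_naa.index)):
            mm = med_mrt.get(d, np.nan)
            mn = med_naa.get(d, np.nan)
            rows.append(
                {
                    "participant_id": pid,
                    "date": d,
                    "daily_median_mrt": mm,
                    "daily_median_naa": mn,
                    "relative_daily_rrt": (1.0 - mm / base_mrt) * 100.0 if np.isfinite(mm) else np.nan,
                    "relative_daily_raa": (mn / base_naa - 1.0) * 100.0 if np.isfinite(mn) else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=[
        "participant_id", "date", "daily_median_mrt", "daily_median_naa",
        "relative_daily_rrt", "relative_daily_raa",
    ])
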