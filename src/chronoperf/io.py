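"""Readers and writers for the four on-disk record formats.

* ``tasks.jsonl`` — one JSON object per task battery.
* ``sleep.csv`` — one row per sleep session; stage columns optional.
* ``minutes.csv`` — minute streams, wide (one column per channel) or long
  (``timestamp, channel, value``); the dialect is auto-detected from the
  header. ``resting_hr`` rides along as its own channel/column, one value
  per day.
* ``schedule.csv`` — one row per (participant, date) with a work/free label.

All timestamps are ISO-8601 naive local time. Readers validate via the
record types and report the offending line/row on failure.
"""

from __future__ import annotations

import csv
import json
import warnings
from datetime import date, datetime
from pathlib import Path

import pandas as pd

from .records import (
    CHANNELS,
    MinuteStream,
    PvtResponse,
    RecordValidationError,
    Schedule,
    SleepSession,
    TaskSession,
)

STAGE_COLUMNS = {"rem": "rem_minutes", "light": "light_minutes", "deep": "deep_minutes", "awake": "awake_minutes"}


def _parse_ts(raw: str, where: str) -> datetime:
    try:
        return datetime.fromisoformat(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: non-ISO timestamp {raw!r}") from exc


# ---------------------------------------------------------------- tasks.jsonl

def read_task_sessions(path: str | Path) -> list[TaskSession]:
    """Read a JSONL file of task batteries, sorted by (participant, timestamp)."""
    sessions: list[TaskSession] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            try:
                sessions.append(
                    TaskSession(
                        participant_id=str(obj["participant_id"]),
                        timestamp=_parse_ts(obj["timestamp"], f"{path} line {lineno}"),
                        pvt_responses=[PvtResponse(float(rt), bool(fs)) for rt, fs in obj.get("pvt_responses", [])],
                        add_attempts=int(obj.get("add_attempts", 0)),
                        kss=obj.get("kss"),
                        caffeine_last_hour=obj.get("caffeine_last_hour"),
                    )
                )
            except (KeyError, TypeError, RecordValidationError) as exc:
                raise ValueError(f"{path}: invalid task session on line {lineno}: {exc}") from exc
    sessions.sort()
    return sessions


def write_task_sessions(sessions: list[TaskSession], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(sessions):
            obj = {
                "participant_id": s.participant_id,
                "timestamp": s.timestamp.isoformat(timespec="minutes"),
                "pvt_responses": [[r.response_time_ms, r.false_start] for r in s.pvt_responses],
                "add_attempts": s.add_attempts,
                "kss": s.kss,
                "caffeine_last_hour": s.caffeine_last_hour,
            }
            fh.write(json.dumps(obj) + "\n")


# ----------------------------------------------------------------- sleep.csv

SLEEP_FIELDS = [
    "participant_id", "start", "end", "minutes_asleep",
    "rem_minutes", "light_minutes", "deep_minutes", "awake_minutes",
    "efficiency", "awakenings_gt5min", "onset_latency",
]


def _opt_float(v: str) -> float | None:
    return float(v) if v not in ("", None) else None


def read_sleep_sessions(path: str | Path) -> list[SleepSession]:
    """Read sleep sessions from CSV, sorted by start.

    Overlapping sessions for one participant trigger a warning but both are
    kept (the downstream nightly selection keeps the longest per wake date).
    """
    sessions: list[SleepSession] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rowno, row in enumerate(csv.DictReader(fh), start=2):
            where = f"{path} row {rowno}"
            stage_vals = {st: _opt_float(row.get(col) or "") for st, col in STAGE_COLUMNS.items()}
            stages = {st: v for st, v in stage_vals.items() if v is not None} or None
            try:
                sessions.append(
                    SleepSession(
                        participant_id=str(row["participant_id"]),
                        start=_parse_ts(row["start"], where),
                        end=_parse_ts(row["end"], where),
                        minutes_asleep=_opt_float(row.get("minutes_asleep") or ""),
                        stage_minutes=stages,
                        efficiency=_opt_float(row.get("efficiency") or ""),
                        awakenings_gt5min=(int(float(row["awakenings_gt5min"])) if row.get("awakenings_gt5min") else None),
                        onset_latency=_opt_float(row.get("onset_latency") or ""),
                    )
                )
            except RecordValidationError as exc:
                raise ValueError(f"{where}: {exc}") from exc
    sessions.sort(key=lambda s: (s.participant_id, s.start))
    for a, b in zip(sessions, sessions[1:]):
        if a.participant_id == b.participant_id and b.start < a.end:
            warnings.warn(
                f"{a.participant_id}: overlapping sleep sessions at {b.start} (kept both)",
                stacklevel=2,
            )
    sessions.sort(key=lambda s: s.start)
    return sessions


def write_sleep_sessions(sessions: list[SleepSession], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=SLEEP_FIELDS)
        w.writeheader()
        for s in sorted(sessions, key=lambda s: (s.participant_id, s.start)):
            row = {
                "participant_id": s.participant_id,
                "start": s.start.isoformat(timespec="minutes"),
                "end": s.end.isoformat(timespec="minutes"),
                "minutes_asleep": "" if s.minutes_asleep is None else s.minutes_asleep,
                "efficiency": "" if s.efficiency is None else s.efficiency,
                "awakenings_gt5min": "" if s.awakenings_gt5min is None else s.awakenings_gt5min,
                "onset_latency": "" if s.onset_latency is None else s.onset_latency,
            }
            for st, col in STAGE_COLUMNS.items():
                v = (s.stage_minutes or {}).get(st)
                row[col] = "" if v is None else v
            w.writerow(row)


# --------------------------------------------------------------- minutes.csv

def _streams_from_wide(df: pd.DataFrame, path) -> dict[str, MinuteStream]:
    out: dict[str, MinuteStream] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.set_index("timestamp")
        resting: dict[date, float] = {}
        if "resting_hr" in grp.columns:
            rh = grp["resting_hr"].dropna()
            for d, sub in rh.groupby(rh.index.date):
                resting[d] = float(sub.iloc[0])
        cols = [c for c in CHANNELS if c in grp.columns]
        out[str(pid)] = MinuteStream(str(pid), grp[cols], resting_hr=resting)
    return out


def read_minute_streams(path: str | Path) -> dict[str, MinuteStream]:
    """Read minute streams for all participants in a CSV file.

    Wide format has one column per channel; long format has
    ``participant_id,timestamp,channel,value`` rows (``resting_hr`` is a
    channel carrying one value per day).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    if "participant_id" not in df.columns or "timestamp" not in df.columns:
        raise ValueError(f"{path}: minutes CSV needs participant_id and timestamp columns")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable timestamp: {exc}") from exc
    if "channel" in df.columns:  # long format
        bad = set(df["channel"].unique()) - set(CHANNELS) - {"resting_hr"}
        if bad:
            raise ValueError(f"{path}: unknown channels {sorted(bad)}")
        num = pd.to_numeric(df["value"], errors="coerce")
        if num.isna().gt(df["value"].isna()).any():
            idx = int(num.index[num.isna() & df["value"].notna()][0])
            raise ValueError(f"{path}: unparseable numeric value at row index {idx}")
        df["value"] = num
        df = df.pivot_table(
            index=["participant_id", "timestamp"], columns="channel", values="value", aggfunc="last"
        ).reset_index()
        df.columns.name = None
    else:
        for c in df.columns:
            if c in CHANNELS or c == "resting_hr":
                num = pd.to_numeric(df[c], errors="coerce")
                bad = num.isna() & df[c].notna()
                if bad.any():
                    raise ValueError(f"{path}: unparseable numeric in {c} at row index {int(bad.idxmax())}")
                df[c] = num
    return _streams_from_wide(df, path)


def read_minute_stream(path: str | Path, participant_id: str | None = None) -> MinuteStream:
    """Read a single participant's minute stream.

    With more than one participant in the file, ``participant_id`` selects
    which; an empty file yields an empty stream.
    """
    streams = read_minute_streams(path)
    if participant_id is not None:
        if participant_id not in streams:
            return MinuteStream(participant_id)
        return streams[participant_id]
    if len(streams) > 1:
        raise ValueError(f"{path}: multiple participants present; specify participant_id")
    if not streams:
        return MinuteStream("")
    return next(iter(streams.values()))


def write_minute_streams(streams: dict[str, MinuteStream] | list[MinuteStream], path: str | Path) -> None:
    """Write streams in wide format."""
    if isinstance(streams, dict):
        streams = list(streams.values())
    frames = []
    for st in streams:
        f = st.frame.copy()
        f.insert(0, "participant_id", st.participant_id)
        if st.resting_hr:
            rh = pd.Series(index=f.index, dtype=float)
            dates = pd.Series(f.index.date, index=f.index)
            first_of_day = ~dates.duplicated()
            rh[first_of_day] = [st.resting_hr.get(d) for d in dates[first_of_day]]
            f["resting_hr"] = rh
        frames.append(f.reset_index(names="timestamp"))
    if frames:
        out = pd.concat(frames, ignore_index=True)
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    else:
        out = pd.DataFrame(columns=["participant_id", "timestamp", *CHANNELS])
    out.to_csv(path, index=False)


# -------------------------------------------------------------- schedule.csv

def read_schedules(path: str | Path) -> dict[str, Schedule]:
    labels: dict[str, dict[date, str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for rowno, row in enumerate(csv.DictReader(fh), start=2):
            pid = str(row["participant_id"])
            try:
                d = date.fromisoformat(row["date"])
            except ValueError as exc:
                raise ValueError(f"{path} row {rowno}: bad date {row['date']!r}") from exc
            lab = row["label"].strip()
            if lab not in ("work", "free"):
                raise ValueError(f"{path} row {rowno}: label must be work/free, got {lab!r}")
            labels.setdefault(pid, {})[d] = lab
    return {pid: Schedule(pid, labs) for pid, labs in labels.items()}


def write_schedules(schedules: dict[str, Schedule] | list[Schedule], path: str | Path) -> None:
    if isinstance(schedules, dict):
        schedules = list(schedules.values())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "date", "label"])
        for sch in schedules:
            for d in sorted(sch.labels):
                w.writerow([sch.participant_id, d.isoformat(), sch.labels[d]])
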