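"""End-to-end analysis orchestration.

``run_analysis`` chains the pipeline stages — read, participant inclusion,
session scoring, chronotype/night metrics, momentary features, merging,
repeated-measures correlation and cosinor fitting — and emits CSV tables:

* ``table_sleep_daily.csv`` — previous-night and weekly sleep features vs
  relative daily alertness/throughput (r_rm, CI, p).
* ``table_momentary.csv`` — time since waking, heart rate and activity
  features vs session-level relative scores.
* ``table_cosinor.csv`` — 24 h cosinor acrophases of both scores by time of
  day and by internal time.
* ``descriptives.csv`` — count/min/max/mean/SD of the analysis variables.
* ``manifest.json`` — config hash and row counts at every filter stage, so
  attrition is auditable on any dataset.

Any stage failure aborts with the stage name and the row-count context
collected so far.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chrono, io as cio, scoring
from .features import features_frame, momentary_feature_vector
from .records import clock_hours
from .stats import Cosinor, RepeatedMeasuresCorrelation

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Paths, thresholds and options for a full pipeline run."""

    tasks_path: str
    sleep_path: str
    schedule_path: str
    minutes_path: str | None = None
    output_dir: str = "analysis_out"
    rt_threshold_ms: float = 800.0
    sd_limit: float = 3.0
    min_tasks: int = 42
    windows: tuple[int, ...] = (10, 60)
    epoch_days: int = 7
    cosinor_period: float = 24.0
    ci_level: float = 0.95
    mean_method: str = "circular"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.rt_threshold_ms <= 0 or self.sd_limit <= 0 or self.min_tasks <= 0:
            raise ValueError("thresholds must be positive")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


#: (column, human label) pairs for the daily sleep-feature tables
DAILY_FEATURES = [
    ("prev_duration", "Previous night's sleep duration"),
    ("weekly_sleep_debt", "Average nightly sleep debt over previous week"),
    ("prev_sleep_shift", "Sleep shift"),
    ("prev_sleep_end", "Sleep end time"),
    ("prev_rem_minutes", "Duration of REM sleep"),
    ("prev_light_minutes", "Duration of light sleep"),
    ("prev_deep_minutes", "Duration of deep sleep"),
]

#: (column, human label) for the momentary tables
MOMENTARY_FEATURES = [
    ("time_since_wake", "Time since waking up"),
    ("current_hr", "Current heart rate"),
    ("resting_hr", "Resting heart rate"),
    ("heart_rate_mean_60", "Average heart rate over last 60 minutes"),
    ("heart_rate_mean_10", "Average heart rate over last 10 minutes"),
    ("heart_rate_var_60", "Variance in heart rate over last 60 minutes"),
    ("heart_rate_var_10", "Variance in heart rate over last 10 minutes"),
    ("calories_mean_60", "Average calories burnt over last 60 minutes"),
    ("calories_mean_10", "Average calories burnt over last 10 minutes"),
    ("calories_var_60", "Variance in calories burnt over last 60 minutes"),
    ("calories_var_10", "Variance in calories burnt over last 10 minutes"),
    ("distance_mean_60", "Average distance traveled over last 60 minutes"),
    ("distance_mean_10", "Average distance traveled over last 10 minutes"),
    ("distance_var_60", "Variance in distance traveled over last 60 minutes"),
    ("distance_var_10", "Variance in distance traveled over last 10 minutes"),
    ("steps_mean_60", "Average steps walked over last 60 minutes"),
    ("steps_mean_10", "Average steps walked over last 10 minutes"),
    ("steps_var_60", "Variance in steps walked over last 60 minutes"),
    ("steps_var_10", "Variance in steps walked over last 10 minutes"),
]

OUTCOMES_DAILY = [("relative_daily_rrt", "alertness"), ("relative_daily_raa", "cognitive_throughput")]
OUTCOMES_SESSION = [("rrt", "alertness"), ("raa", "cognitive_throughput")]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and row counts."""

    def __init__(self, stage: str, counts: dict, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed ({cause}); row counts so far: {counts}")
        self.stage = stage
        self.counts = counts


def rmcorr_table(frame: pd.DataFrame, pairs, outcomes, min_pairs: int = 3) -> pd.DataFrame:
    """Rows of (feature, outcome, r_rm, CI, p, n_obs, n_subjects, df)."""
    rows = []
    for col, label in pairs:
        for out_col, out_label in outcomes:
            row = {"feature": label, "feature_col": col, "outcome": out_label}
            try:
                if col not in frame.columns or out_col not in frame.columns:
                    raise ValueError("column missing")
                res = RepeatedMeasuresCorrelation(
                    frame[col], frame[out_col], frame["participant_id"]
                ).fit()
                row.update(
                    r_rm=res.r_rm, ci_low=res.ci_low, ci_high=res.ci_high,
                    p_value=res.p_value, n_obs=res.n_obs, n_subjects=res.n_subjects, df=res.df,
                )
            except ValueError:
                row.update(r_rm=np.nan, ci_low=np.nan, ci_high=np.nan,
                           p_value=np.nan, n_obs=0, n_subjects=0, df=0)
            rows.append(row)
    return pd.DataFrame(rows, columns=["feature", "feature_col", "outcome", "r_rm",
                                       "ci_low", "ci_high", "p_value", "n_obs", "n_subjects", "df"])


def cosinor_table(frame: pd.DataFrame, period: float = 24.0) -> pd.DataFrame:
    """Cosinor acrophases of both scores by time of day and internal time."""
    rows = []
    for t_col, t_label in [("time_of_day", "Time of day"), ("internal_time", "Internal time")]:
        for out_col, out_label in OUTCOMES_SESSION:
            row = {"time_axis": t_label, "outcome": out_label}
            try:
                sub = frame[[t_col, out_col]].dropna()
                fit = Cosinor(sub[t_col], sub[out_col], period=period).fit()
                row.update(
                    mesor=fit.mesor, amplitude=fit.amplitude,
                    acrophase_hours=fit.acrophase, acrophase=fit.acrophase_str(),
                    p_value=fit.amplitude_p, n_obs=fit.n_obs,
                )
            except (ValueError, KeyError):
                row.update(mesor=np.nan, amplitude=np.nan, acrophase_hours=np.nan,
                           acrophase="", p_value=np.nan, n_obs=0)
            rows.append(row)
    return pd.DataFrame(rows, columns=["time_axis", "outcome", "mesor", "amplitude",
                                       "acrophase_hours", "acrophase", "p_value", "n_obs"])


def binned_summary(frame: pd.DataFrame, value_col: str, bin_hours: int = 4) -> pd.DataFrame:
    """Per-bin mean and SEM of a score by time of day.

    Bins align at midnight ([0, bin), [bin, 2*bin), ...); empty bins are
    omitted. SEM = SD / sqrt(n) with sample SD.
    """
    if 24 % bin_hours:
        raise ValueError("bin_hours must divide 24")
    df = frame.dropna(subset=[value_col]).copy()
    hours = df["timestamp"].map(clock_hours) if "timestamp" in df else df["time_of_day"]
    df["bin_start"] = (hours // bin_hours).astype(int) * bin_hours
    rows = []
    for b, grp in df.groupby("bin_start", sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append({"bin_start": int(b), "bin_end": int(b) + bin_hours,
                     "mean": float(vals.mean()), "sem": sem, "n": len(vals)})
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "mean", "sem", "n"])


def build_daily_frame(daily: pd.DataFrame, nights_by_pid, epoch_days: int = 7) -> pd.DataFrame:
    """Join each daily score with its previous night and weekly aggregates."""
    rows = []
    for _, r in daily.iterrows():
        pid, d = r["participant_id"], r["date"]
        nights = nights_by_pid.get(pid, [])
        night = next((n for n in nights if n.wake_date == d), None)
        row = dict(r)
        if night is not None:
            row.update(
                prev_duration=night.duration,
                prev_rem_minutes=night.rem_minutes,
                prev_light_minutes=night.light_minutes,
                prev_deep_minutes=night.deep_minutes,
                prev_sleep_shift=night.sleep_shift,
                prev_sleep_end=night.sleep_end,
                prev_sleep_debt=night.sleep_debt,
            )
        week = chrono.weekly_aggregates(nights, d, epoch_days) if nights else None
        if week is not None:
            row.update(weekly_sleep_debt=week.sleep_debt, weekly_sleep_shift=week.sleep_shift,
                       weekly_duration=week.duration, weekly_imputed=week.imputed_nights)
        rows.append(row)
    return pd.DataFrame(rows)


def describe_table(frame: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    rows = []
    for col in columns:
        if col not in frame.columns:
            continue
        vals = pd.to_numeric(frame[col], errors="coerce").dropna()
        if vals.empty:
            continue
        rows.append({"variable": col, "n": len(vals), "min": vals.min(), "max": vals.max(),
                     "mean": vals.mean(), "sd": vals.std(ddof=1)})
    return pd.DataFrame(rows, columns=["variable", "n", "min", "max", "mean", "sd"])


def run_analysis(config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Run the full pipeline; returns the output tables and writes them."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    counts: dict[str, int] = {}
    stage = "read_inputs"
    try:
        tasks = cio.read_task_sessions(config.tasks_path)
        sleep = cio.read_sleep_sessions(config.sleep_path)
        schedules = cio.read_schedules(config.schedule_path)
        streams = cio.read_minute_streams(config.minutes_path) if config.minutes_path else {}
        counts["tasks_read"] = len(tasks)
        counts["sleep_sessions_read"] = len(sleep)

        stage = "participant_inclusion"
        kept = scoring.include_participants(tasks, config.min_tasks)
        tasks = [t for t in tasks if t.participant_id in kept]
        counts["tasks_after_inclusion"] = len(tasks)
        logger.info("inclusion filter kept %d participants, %d tasks", len(kept), len(tasks))

        stage = "session_scoring"
        scores = scoring.score_sessions(tasks, config.rt_threshold_ms, config.sd_limit)
        sdf = scoring.scores_frame(scores)
        counts["sessions_retained_pvt"] = int(sdf["retained_pvt"].sum())
        counts["sessions_retained_add"] = int(sdf["retained_add"].sum())

        stage = "chronobiology"
        profiles, nights_by_pid = {}, {}
        for pid in sorted(kept):
            p_sleep = [s for s in sleep if s.participant_id == pid]
            if not p_sleep or pid not in schedules:
                continue
            prof = chrono.chronotype_msf(p_sleep, schedules[pid], config.mean_method)
            profiles[pid] = prof
            nights_by_pid[pid] = chrono.night_metrics(p_sleep, prof)
        counts["participants_with_chronotype"] = len(profiles)
        counts["nights"] = sum(len(v) for v in nights_by_pid.values())

        stage = "daily_merge"
        daily = scoring.daily_relative_scores(scores)
        daily_frame = build_daily_frame(daily, nights_by_pid, config.epoch_days)
        counts["daily_scores"] = len(daily_frame)
        counts["daily_with_prev_night"] = int(daily_frame["prev_duration"].notna().sum()) \
            if "prev_duration" in daily_frame else 0

        stage = "momentary_features"
        feats = []
        for t in tasks:
            stream = streams.get(t.participant_id)
            if stream is not None:
                feats.append(momentary_feature_vector(t, stream, config.windows))
        session_frame = sdf.copy()
        if feats:
            fdf = features_frame(feats)
            session_frame = session_frame.merge(fdf, on=["participant_id", "timestamp"], how="left")
        session_frame["time_of_day"] = session_frame["timestamp"].map(clock_hours)
        session_frame["internal_time"] = [
            chrono.internal_time(ts, profiles[pid].msf) if pid in profiles else np.nan
            for pid, ts in zip(session_frame["participant_id"], session_frame["timestamp"])
        ]
        session_frame["time_since_wake"] = [
            chrono.time_since_wake(ts, nights_by_pid[pid]) if pid in nights_by_pid else np.nan
            for pid, ts in zip(session_frame["participant_id"], session_frame["timestamp"])
        ]
        counts["sessions_with_linked_sleep"] = int(session_frame["time_since_wake"].notna().sum())

        stage = "correlations"
        table_daily = rmcorr_table(daily_frame, DAILY_FEATURES, OUTCOMES_DAILY)
        table_momentary = rmcorr_table(session_frame, MOMENTARY_FEATURES, OUTCOMES_SESSION)

        stage = "cosinor"
        table_cos = cosinor_table(session_frame, config.cosinor_period)

        stage = "summaries"
        desc = describe_table(
            session_frame,
            ["mrt", "rrt", "naa", "raa", "time_of_day", "internal_time", "time_since_wake",
             "current_hr", "resting_hr", "heart_rate_mean_60", "steps_mean_10"],
        )
        binned = pd.concat(
            [binned_summary(session_frame, c, 4).assign(score=c) for c in ("rrt", "raa")],
            ignore_index=True,
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, counts, exc) from exc

    tables = {
        "table_sleep_daily": table_daily,
        "table_momentary": table_momentary,
        "table_cosinor": table_cos,
        "descriptives": desc,
        "binned_scores": binned,
        "daily_frame": daily_frame,
        "session_frame": session_frame,
    }
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("table_sleep_daily", "table_momentary", "table_cosinor", "descriptives", "binned_scores"):
        tables[name].to_csv(outdir / f"{name}.csv", index=False)
    manifest = {
        "config": {k: str(v) for k, v in config.as_dict().items()},
        "config_hash": hashlib.sha256(
            json.dumps(config.as_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "row_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables
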