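"""Two-process synthetic cohort generator.

Generates complete study datasets — work/free schedules, nightly sleep with
stage composition, minute-level heart-rate/activity streams, and PVT+ADD
task batteries — for three population groups (regular workers, rotating
shift workers, graduate students). Task outcomes follow a two-process
performance model: a circadian component C (24 h cosine peaking a fixed
offset after the individual's chronotype) and a homeostatic component H
(sleep pressure rising as a saturating exponential while awake and decaying
exponentially during sleep), plus configurable couplings from the previous
night's sleep, the sleep-timing misalignment, and momentary heart rate and
activity. Latent alertness maps to a session median reaction time by a
decreasing link; latent throughput maps to an addition count by an
increasing link.

Everything is reproducible bit-for-bit from (config, seed), and the latent
ground truth (per-participant chronotype, per-task C, H and coupling
contributions before noise) is returned alongside the observable records so
recovery tests can compare pipeline estimates against it.

Default calibration: nightly durations average ~433 min with free nights
~46 min longer than work nights; stage fractions centre on 18% REM, 53%
light, 16% deep (of total session duration); ~2.8 task batteries per day
with a 2 h minimum gap; circadian acrophase 13.5 h after the chronotype;
homeostatic time constants 18.2 h (buildup) and 4.2 h (decay).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .records import MinuteStream, PvtResponse, Schedule, SleepSession, TaskSession, clock_hours, combine_clock

GROUPS = ("regular", "shift", "student")


@dataclass
class Couplings:
    """Linear couplings feeding the latent performance components.

    Units: percent of latent alertness/throughput per natural unit of the
    driver (minutes for sleep features, bpm for heart rate, steps/min for
    activity; homeostatic pressure is dimensionless in [0, 1]). Signs follow
    the directions the analysis is meant to recover: longer/richer sleep and
    arousal help, later sleep and sleep pressure hurt.
    """

    sleep_duration_alertness: float = 0.02
    rem_alertness: float = 0.04
    light_alertness: float = 0.025
    sleep_shift_throughput: float = -0.015
    sleep_end_throughput: float = -0.01
    homeostatic_alertness: float = 8.0
    # arousal couplings act on the smoothed window signals (60-min heart-rate
    # mean, 10-min step mean), whose within-subject spread is a few units, so
    # their per-unit magnitudes are larger than the sleep couplings'
    hr_alertness: float = 0.3
    hr_throughput: float = 0.45
    activity_alertness: float = 0.25
    activity_throughput: float = 0.35

    def zeroed(self) -> "Couplings":
        return Couplings(**{k: 0.0 for k in asdict(self)})


@dataclass
class SimConfig:
    """Generator parameters; defaults define the emulated study conditions."""

    n_regular: int = 6
    n_shift: int = 5
    n_student: int = 5
    days: int = 42
    start_date: date = date(2019, 3, 4)  # a Monday

    # nightly sleep durations (minutes): mean, sd per day type
    work_sleep_minutes: tuple[float, float] = (420.0, 80.0)
    free_sleep_minutes: tuple[float, float] = (466.0, 80.0)
    min_sleep_minutes: float = 181.0
    max_sleep_minutes: float = 760.0

    # stage fractions of total session duration
    stage_fraction_mean: dict[str, float] = field(
        default_factory=lambda: {"rem": 0.1818, "light": 0.5292, "deep": 0.1592}
    )
    stage_fraction_sd: dict[str, float] = field(
        default_factory=lambda: {"rem": 0.0532, "light": 0.0695, "deep": 0.051}
    )

    # chronotype (true uncorrected mid-sleep on free days), hours
    msf_mean: dict[str, float] = field(
        default_factory=lambda: {"regular": 3.6, "shift": 4.4, "student": 5.0}
    )
    msf_sd: dict[str, float] = field(
        default_factory=lambda: {"regular": 0.7, "shift": 1.2, "student": 1.0}
    )
    free_midsleep_jitter_hours: float = 0.5

    # task battery process
    tasks_per_day: float = 2.81
    min_gap_minutes: float = 120.0

    # two-process model
    circadian_amplitude_alertness: float = 3.0  # percent
    circadian_amplitude_throughput: float = 3.0
    acrophase_offset_hours: float = 13.5  # peak this long after MSF
    tau_wake_hours: float = 18.2
    tau_sleep_hours: float = 4.2

    couplings: Couplings = field(default_factory=Couplings)
    alertness_noise_sd: float = 7.0  # percent
    throughput_noise_sd: float = 11.0

    # outcome links
    base_mrt_ms: float = 355.0
    base_naa: float = 18.0
    participant_mrt_log_sd: float = 0.15  # between-person baseline spread
    participant_naa_sd: float = 2.5
    pvt_stimuli: int = 16
    pvt_rt_spread: float = 0.06  # lognormal sigma of stimulus RTs around MRT
    false_start_prob: float = 0.02

    # minute streams
    include_streams: bool = True
    resting_hr_mean: float = 66.0
    resting_hr_sd: float = 8.0
    hr_wake_offset: float = 10.0
    hr_sleep_dip: float = 6.0
    hr_diurnal_amplitude: float = 5.0
    hr_noise_sd: float = 5.0
    activity_bout_prob: float = 0.04
    activity_bout_steps: float = 70.0

    # opt-in missingness
    missing_night_rate: float = 0.0
    stream_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.min_gap_minutes < 0:
            raise ValueError("min_gap_minutes must be >= 0")
        for sd in (self.work_sleep_minutes[1], self.free_sleep_minutes[1],
                   self.alertness_noise_sd, self.throughput_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")

    @property
    def reference_sleep_minutes(self) -> float:
        """Pooled expected nightly duration at a 5:2 work:free mix."""
        return (5 * self.work_sleep_minutes[0] + 2 * self.free_sleep_minutes[0]) / 7.0

    def participants(self) -> list[tuple[str, str]]:
        prefixes = {"regular": "R", "shift": "S", "student": "G"}  # G: graduate student
        out = []
        for group, n in (("regular", self.n_regular), ("shift", self.n_shift), ("student", self.n_student)):
            out.extend((f"{prefixes[group]}{i + 1:02d}", group) for i in range(n))
        return out


# ----------------------------------------------------------- process models

def circadian_value(t: datetime, msf: float, offset: float, amplitude: float) -> float:
    """Circadian component at time ``t``: amplitude * cos(2pi (InT - offset)/24).

    Maximal exactly ``offset`` hours after the chronotype's mid-sleep point.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    int_h = (clock_hours(t) - msf) % 24.0
    return amplitude * math.cos(2 * math.pi * (int_h - offset) / 24.0)


def homeostatic_value(minutes_awake: float, s0: float = 0.0, tau_wake_hours: float = 18.2) -> float:
    """Sleep pressure after ``minutes_awake`` awake, starting from ``s0``."""
    if tau_wake_hours <= 0:
        raise ValueError("tau must be positive")
    return 1.0 - (1.0 - s0) * math.exp(-minutes_awake / (tau_wake_hours * 60.0))


def homeostatic_decay(minutes_asleep: float, s0: float, tau_sleep_hours: float = 4.2) -> float:
    """Sleep pressure after ``minutes_asleep`` asleep, starting from ``s0``."""
    if tau_sleep_hours <= 0:
        raise ValueError("tau must be positive")
    return s0 * math.exp(-minutes_asleep / (tau_sleep_hours * 60.0))


class HomeostatTrajectory:
    """Piecewise sleep-pressure trajectory over alternating wake/sleep bouts."""

    def __init__(
        self,
        sleep_bouts: list[tuple[datetime, datetime]],
        tau_wake_hours: float = 18.2,
        tau_sleep_hours: float = 4.2,
        initial: float = 0.1,
    ) -> None:
        self.tau_w, self.tau_s = tau_wake_hours, tau_sleep_hours
        bouts = sorted(sleep_bouts)
        if not bouts:
            raise ValueError("need at least one sleep bout")
        t0 = bouts[0][0] - timedelta(hours=16)
        # checkpoints: (time, pressure at time, state until next checkpoint)
        self.points: list[tuple[datetime, float, str]] = [(t0, initial, "wake")]
        s, t = initial, t0
        for start, end in bouts:
            s = homeostatic_value((start - t).total_seconds() / 60.0, s, self.tau_w)
            self.points.append((start, s, "sleep"))
            s = homeostatic_decay((end - start).total_seconds() / 60.0, s, self.tau_s)
            self.points.append((end, s, "wake"))
            t = end
        self.times = [p[0] for p in self.points]

    def value(self, t: datetime) -> float:
        i = bisect_right(self.times, t) - 1
        if i < 0:
            return self.points[0][1]
        t0, s0, state = self.points[i]
        dt = (t - t0).total_seconds() / 60.0
        if state == "wake":
            return homeostatic_value(dt, s0, self.tau_w)
        return homeostatic_decay(dt, s0, self.tau_s)


# --------------------------------------------------------------- sleep layer

def _truncnorm(rng, mean, sd, lo, hi):
    v = rng.normal(mean, sd)
    return float(min(max(v, lo), hi))


def _shift_blocks(rng, days: int) -> list[str]:
    """Per-date shift type for a rotating-shift worker: day/evening/night/off."""
    out: list[str] = []
    while len(out) < days + 1:
        kind = rng.choice(["day", "evening", "night"])
        out.extend([kind] * int(rng.integers(3, 7)))
        out.extend(["off"] * int(rng.integers(1, 3)))
    return out[: days + 1]


_SHIFT_WAKE = {"day": 6.0, "evening": 9.0, "night": 15.0}


def simulate_sleep_schedule(
    group: str,
    days: int,
    rng: np.random.Generator,
    config: SimConfig | None = None,
    participant_id: str = "P01",
    msf_true: float | None = None,
) -> tuple[list[SleepSession], Schedule, float]:
    """Nightly sleep sessions and work/free labels for one participant.

    Returns (sessions, schedule, true uncorrected mid-sleep). One session is
    generated per wake date over ``days`` dates starting the day after the
    config start date. Regular workers keep a Mon-Fri pattern with stable
    bedtimes; students run later and more variable with occasional weekend
    work; shift workers rotate through day/evening/night blocks, which
    displaces sleep by many hours. Free-night mid-sleep centres on the
    participant's true chronotype.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if days < 7:
        raise ValueError("need at least 7 days so free days exist for the chronotype")
    config = config or SimConfig()
    if msf_true is None:
        msf_true = rng.normal(config.msf_mean[group], config.msf_sd[group]) % 24.0
    start = config.start_date
    wake_dates = [start + timedelta(days=k + 1) for k in range(days)]
    shift_types = _shift_blocks(rng, days) if group == "shift" else None

    labels: dict[date, str] = {start: "free"}
    sessions: list[SleepSession] = []
    prev_end: datetime | None = None
    for k, d in enumerate(wake_dates):
        if group == "regular":
            label = "work" if d.weekday() < 5 else "free"
        elif group == "student":
            if d.weekday() < 5:
                label = "work"
            elif d.weekday() == 5:
                label = "work" if rng.random() < 0.25 else "free"
            else:
                label = "free"
        else:
            label = "free" if shift_types[k] == "off" else "work"
        labels[d] = label

        mean, sd = config.free_sleep_minutes if label == "free" else config.work_sleep_minutes
        dur = _truncnorm(rng, mean, sd, config.min_sleep_minutes, config.max_sleep_minutes)
        if label == "free":
            mid_clock = (msf_true + rng.normal(0.0, config.free_midsleep_jitter_hours)) % 24.0
            anchor = d if mid_clock < 12.0 else d - timedelta(days=1)
            mid = combine_clock(anchor, mid_clock)
            start_dt = mid - timedelta(minutes=dur / 2)
            end_dt = mid + timedelta(minutes=dur / 2)
        else:
            if group == "regular":
                wake = rng.normal(7.0, 0.4)
            elif group == "student":
                wake = rng.normal(8.5, 0.8)
            else:
                wake = rng.normal(_SHIFT_WAKE[shift_types[k]], 0.5)
            end_dt = combine_clock(d, wake % 24.0)
            start_dt = end_dt - timedelta(minutes=dur)
        if prev_end is not None and start_dt < prev_end + timedelta(minutes=30):
            start_dt = prev_end + timedelta(minutes=30)
            if end_dt <= start_dt + timedelta(minutes=config.min_sleep_minutes):
                end_dt = start_dt + timedelta(minutes=config.min_sleep_minutes)
        start_dt = start_dt.replace(second=0, microsecond=0)
        end_dt = end_dt.replace(second=0, microsecond=0)
        dur = (end_dt - start_dt).total_seconds() / 60.0
        prev_end = end_dt

        fr = {st: max(rng.normal(config.stage_fraction_mean[st], config.stage_fraction_sd[st]), 0.02)
              for st in ("rem", "light", "deep")}
        tot = sum(fr.values())
        if tot > 0.98:
            fr = {st: v * 0.98 / tot for st, v in fr.items()}
        stage_minutes = {st: round(v * dur, 1) for st, v in fr.items()}
        stage_minutes["awake"] = round(dur - sum(stage_minutes.values()), 1)
        asleep = dur - stage_minutes["awake"]
        sessions.append(
            SleepSession(
                participant_id=participant_id,
                start=start_dt,
                end=end_dt,
                minutes_asleep=round(asleep, 1),
                stage_minutes=stage_minutes if dur > 180 else None,
                efficiency=round(_truncnorm(rng, 90.0, 6.0, 27.0, 100.0), 1),
                awakenings_gt5min=int(rng.poisson(3.0)),
                onset_latency=round(float(rng.exponential(8.0)), 1),
            )
        )
    return sessions, Schedule(participant_id, labels), float(msf_true)


# -------------------------------------------------------------- stream layer

def simulate_streams(
    nights: list[SleepSession],
    config: SimConfig,
    rng: np.random.Generator,
    msf_true: float,
    participant_id: str,
    resting_base: float,
) -> MinuteStream:
    """Minute heart-rate/activity streams over the participant's study span.

    Waking heart rate sits above the day's resting rate with a chronotype-
    aligned diurnal sinusoid and activity-coupled bumps; sleep dips below
    resting. Steps/distance/calories come from a minute-level activity bout
    process that is identically zero during sleep.
    """
    span_start = combine_clock(config.start_date, 0.0)
    n_min = (config.days + 2) * 1440
    idx = pd.date_range(span_start, periods=n_min, freq="min")

    asleep = np.zeros(n_min, dtype=bool)
    for s in nights:
        i0 = max(int((s.start - span_start).total_seconds() // 60), 0)
        i1 = min(int((s.end - span_start).total_seconds() // 60), n_min)
        asleep[i0:i1] = True

    day_index = np.arange(n_min) // 1440
    n_days = day_index.max() + 1
    resting_by_day = resting_base + rng.normal(0.0, 1.5, size=n_days)
    resting = resting_by_day[day_index]

    clock = (np.arange(n_min) % 1440) / 60.0
    int_h = (clock - msf_true) % 24.0
    diurnal = config.hr_diurnal_amplitude * np.cos(
        2 * np.pi * (int_h - config.acrophase_offset_hours) / 24.0
    )

    active = (~asleep) & (rng.random(n_min) < config.activity_bout_prob)
    steps = np.where(active, rng.poisson(config.activity_bout_steps, size=n_min), 0).astype(float)
    distance = np.round(steps * 0.0007, 4)
    calories = np.clip(
        np.where(asleep, 1.05, 1.35) + 0.04 * steps + rng.normal(0.0, 0.08, n_min), 0.78, None
    ).round(2)
    floors = np.where(~asleep, rng.poisson(0.005, size=n_min), 0).astype(float)

    hr = (
        resting
        + np.where(asleep, -config.hr_sleep_dip, config.hr_wake_offset)
        + np.where(asleep, 0.3, 1.0) * diurnal
        + 0.2 * steps
        + rng.normal(0.0, config.hr_noise_sd, n_min)
    )
    hr = np.clip(np.round(hr), 35.0, 200.0)

    frame = pd.DataFrame(
        {"heart_rate": hr, "calories": calories, "steps": steps, "distance": distance, "floors": floors},
        index=idx,
    )
    if config.stream_missing_rate > 0:
        gap = rng.random(n_min) < config.stream_missing_rate
        frame.loc[gap, :] = np.nan
    resting_hr = {
        (span_start + timedelta(days=int(k))).date(): float(np.round(resting_by_day[k], 1))
        for k in range(n_days)
    }
    return MinuteStream(participant_id, frame, resting_hr=resting_hr)


# ---------------------------------------------------------------- task layer

def _window_mean(stream: MinuteStream | None, t: datetime, window: int, channel: str) -> float | None:
    if stream is None or channel not in stream.frame.columns:
        return None
    end = pd.Timestamp(t).floor("min")
    sel = stream.frame.loc[end - pd.Timedelta(minutes=window - 1): end, channel].dropna()
    if len(sel) < window / 2:
        return None
    return float(sel.mean())


def simulate_tasks(
    nights: list[SleepSession],
    config: SimConfig,
    rng: np.random.Generator,
    msf_true: float,
    participant_id: str,
    stream: MinuteStream | None,
    resting_base: float,
) -> tuple[list[TaskSession], list[dict]]:
    """Task batteries driven by the two-process performance model.

    Task times are a thinned Poisson process over each day's waking window
    with the configured minimum inter-task gap enforced greedily across the
    whole record. Returns the observable sessions plus per-task latent truth
    rows (C, H, each coupling contribution, noise-free alertness/throughput).
    """
    c = config.couplings
    ref_dur = config.reference_sleep_minutes
    ref_stage = {st: config.stage_fraction_mean[st] * ref_dur for st in ("rem", "light", "deep")}
    traj = HomeostatTrajectory(
        [(s.start, s.end) for s in nights], config.tau_wake_hours, config.tau_sleep_hours
    )
    base_mrt = config.base_mrt_ms * math.exp(rng.normal(0.0, config.participant_mrt_log_sd))
    base_naa = max(config.base_naa + rng.normal(0.0, config.participant_naa_sd), 5.0)

    tasks: list[TaskSession] = []
    truth_rows: list[dict] = []
    last_time: datetime | None = None
    for i, night in enumerate(nights):
        w_start = night.end + timedelta(minutes=20)
        w_end = (nights[i + 1].start if i + 1 < len(nights) else night.end + timedelta(hours=16)) - timedelta(minutes=20)
        total_min = (w_end - w_start).total_seconds() / 60.0
        if total_min < 1:
            continue
        n_tasks = rng.poisson(config.tasks_per_day)
        offsets = np.sort(rng.integers(0, int(total_min), size=n_tasks))
        for off in offsets:
            t = (w_start + timedelta(minutes=int(off))).replace(second=0, microsecond=0)
            if last_time is not None and (t - last_time).total_seconds() / 60.0 < config.min_gap_minutes:
                continue
            last_time = t

            c_alert = circadian_value(t, msf_true, config.acrophase_offset_hours,
                                      config.circadian_amplitude_alertness)
            c_thr = circadian_value(t, msf_true, config.acrophase_offset_hours,
                                    config.circadian_amplitude_throughput)
            h = traj.value(t)

            dur_dev = night.duration_minutes - ref_dur
            if night.stage_minutes is not None:
                rem_dev = night.stage_minutes["rem"] - ref_stage["rem"]
                light_dev = night.stage_minutes["light"] - ref_stage["light"]
            else:
                rem_dev = light_dev = 0.0
            msf_anchor = night.wake_date if msf_true < 12.0 else night.wake_date - timedelta(days=1)
            shift_dev = (night.mid_sleep - combine_clock(msf_anchor, msf_true)).total_seconds() / 60.0
            end_dev = (night.end - combine_clock(night.wake_date, 7.5)).total_seconds() / 60.0

            hr60 = _window_mean(stream, t, 60, "heart_rate")
            act10 = _window_mean(stream, t, 10, "steps")
            hr_dev = 0.0 if hr60 is None else hr60 - (resting_base + config.hr_wake_offset)
            act = 0.0 if act10 is None else act10

            contrib = {
                "c_alert": c_alert,
                "c_thr": c_thr,
                "h": h,
                "homeo_alert": -c.homeostatic_alertness * (h - 0.55),
                "dur_alert": c.sleep_duration_alertness * dur_dev,
                "rem_alert": c.rem_alertness * rem_dev,
                "light_alert": c.light_alertness * light_dev,
                "shift_thr": c.sleep_shift_throughput * shift_dev,
                "end_thr": c.sleep_end_throughput * end_dev,
                "hr_alert": c.hr_alertness * hr_dev,
                "hr_thr": c.hr_throughput * hr_dev,
                "act_alert": c.activity_alertness * act,
                "act_thr": c.activity_throughput * act,
            }
            alert_true = (contrib["c_alert"] + contrib["homeo_alert"] + contrib["dur_alert"]
                          + contrib["rem_alert"] + contrib["light_alert"]
                          + contrib["hr_alert"] + contrib["act_alert"])
            thr_true = (contrib["c_thr"] + contrib["shift_thr"] + contrib["end_thr"]
                        + contrib["hr_thr"] + contrib["act_thr"])
            alert = alert_true + rng.normal(0.0, config.alertness_noise_sd)
            thr = thr_true + rng.normal(0.0, config.throughput_noise_sd)

            mrt = float(np.clip(base_mrt * (1.0 - alert / 100.0), 150.0, 1100.0))
            naa = int(max(round(base_naa * (1.0 + thr / 100.0)), 1))

            responses = [
                PvtResponse(round(float(mrt * math.exp(rng.normal(0.0, config.pvt_rt_spread))), 1), False)
                for _ in range(config.pvt_stimuli)
            ]
            n_fs = rng.binomial(config.pvt_stimuli, config.false_start_prob)
            for _ in range(n_fs):
                responses.insert(int(rng.integers(0, len(responses) + 1)),
                                 PvtResponse(round(float(rng.uniform(80, 250)), 1), True))
            kss = int(np.clip(round(2 + 4 * h + rng.normal(0.0, 1.0)), 1, 9))
            tasks.append(
                TaskSession(
                    participant_id=participant_id,
                    timestamp=t,
                    pvt_responses=responses,
                    add_attempts=naa,
                    kss=kss,
                    caffeine_last_hour=bool(rng.random() < 0.15),
                )
            )
            truth_rows.append(
                {
                    "participant_id": participant_id,
                    "timestamp": t,
                    **contrib,
                    "alertness_true": alert_true,
                    "throughput_true": thr_true,
                    "alertness": alert,
                    "throughput": thr,
                    "mrt": mrt,
                    "naa": naa,
                }
            )
    return tasks, truth_rows


# --------------------------------------------------------------- orchestrator

@dataclass
class SimTruth:
    """Latent ground truth: per-participant, per-night and per-task."""

    participants: pd.DataFrame
    nights: pd.DataFrame
    tasks: pd.DataFrame


@dataclass
class SimulatedCohort:
    """A complete synthetic study dataset plus its generating truth."""

    config: SimConfig
    seed: int
    tasks: list[TaskSession]
    sleep: list[SleepSession]
    schedules: dict[str, Schedule]
    streams: dict[str, MinuteStream]
    truth: SimTruth

    def to_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_task_sessions(self.tasks, outdir / "tasks.jsonl")
        cio.write_sleep_sessions(self.sleep, outdir / "sleep.csv")
        cio.write_schedules(self.schedules, outdir / "schedule.csv")
        if self.streams:
            cio.write_minute_streams(self.streams, outdir / "minutes.csv")
        self.truth.participants.to_csv(outdir / "truth_participants.csv", index=False)
        self.truth.tasks.to_csv(outdir / "truth_tasks.csv", index=False)


def simulate_cohort(config: SimConfig | None = None, seed: int = 0) -> SimulatedCohort:
    """Generate a full cohort deterministically from (config, seed)."""
    config = config or SimConfig()
    root = np.random.SeedSequence([seed, 19])
    participants = config.participants()
    children = root.spawn(len(participants))

    all_tasks: list[TaskSession] = []
    all_sleep: list[SleepSession] = []
    schedules: dict[str, Schedule] = {}
    streams: dict[str, MinuteStream] = {}
    p_rows, truth_rows, night_rows = [], [], []
    for (pid, group), child in zip(participants, children):
        rng = np.random.default_rng(child)
        nights, schedule, msf_true = simulate_sleep_schedule(
            group, config.days, rng, config, participant_id=pid
        )
        resting_base = float(np.clip(rng.normal(config.resting_hr_mean, config.resting_hr_sd), 48.0, 90.0))
        stream = None
        if config.include_streams:
            stream = simulate_streams(nights, config, rng, msf_true, pid, resting_base)
            streams[pid] = stream
        tasks, truths = simulate_tasks(nights, config, rng, msf_true, pid, stream, resting_base)
        recorded = [s for s in nights if not (config.missing_night_rate > 0
                                              and rng.random() < config.missing_night_rate)]
        all_tasks.extend(tasks)
        all_sleep.extend(recorded)
        schedules[pid] = schedule
        p_rows.append({"participant_id": pid, "group": group, "msf_true": msf_true,
                       "resting_hr": resting_base})
        truth_rows.extend(truths)
        night_rows.extend(
            {
                "participant_id": pid,
                "wake_date": s.wake_date,
                "duration": s.duration_minutes,
                "recorded": s in recorded,
            }
            for s in nights
        )

    truth = SimTruth(
        participants=pd.DataFrame(p_rows),
        nights=pd.DataFrame(night_rows),
        tasks=pd.DataFrame(truth_rows),
    )
    all_tasks.sort()
    return SimulatedCohort(
        config=config, seed=seed, tasks=all_tasks, sleep=all_sleep,
        schedules=schedules, streams=streams, truth=truth,
    )
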