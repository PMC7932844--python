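"""Chronotype, sleep need/debt, sleep shift, weekly aggregates and linkage.

Chronotype is quantified as the corrected mid-sleep point on free days:

    MSF = MSF_uc - 0.5 * (SD_f - SN)
    SN  = (N_w * SD_w + N_f * SD_f) / (N_w + N_f)

where MSF_uc is the average mid-sleep clock time over free-day nights, SD_w /
SD_f the mean sleep duration on work / free days, and N_w / N_f the day
counts. The correction removes the oversleep with which people repay
work-week sleep debt on free days. SN doubles as the individual sleep need,
and nightly sleep debt is 1 - duration/SN, which averages to exactly zero
over the nights entering SN.

Internal time InT = ExT - MSF (mod 24) realigns clock time to the
individual's circadian phase. Sleep shift is the signed misalignment between
a night's actual mid-sleep instant and the MSF instant expected for that
wake date; it is a *datetime* difference, not a minimal circular one, so
rotating-shift sleep can legitimately exceed +/-12 h.

Averaging convention: MSF_uc uses the circular mean of mid-sleep clock
times by default; ``mean_method='linear'`` gives a naive mean anchored at
noon (sleep times never span noon in practice) for comparison.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np

from .records import Schedule, SleepSession, combine_clock

logger = logging.getLogger(__name__)

LINK_HORIZON_HOURS = 36.0


def circular_mean_hours(hours) -> float:
    """Circular mean of clock times (fractional hours) on the 24 h circle."""
    h = np.asarray(hours, dtype=float)
    if h.size == 0:
        raise ValueError("circular mean of empty set")
    ang = h * (2 * np.pi / 24.0)
    return float(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) * (24.0 / (2 * np.pi)) % 24.0)


def linear_mean_hours(hours, anchor: float = 12.0) -> float:
    """Naive mean of clock times after unwrapping into [anchor, anchor + 24)."""
    h = np.asarray(hours, dtype=float) % 24.0
    h = np.where(h < anchor, h + 24.0, h)
    return float(h.mean() % 24.0)


def mid_sleep_time(session: SleepSession) -> float:
    """Mid-sleep point of a session as clock hours in [0, 24)."""
    return session.mid_sleep_hours


def nightly_sessions(sessions: list[SleepSession]) -> dict[date, SleepSession]:
    """The 'night' per wake date: the longest session ending on that date.

    Naps (shorter additional sessions on the same wake date) are excluded
    from chronotype, debt and linkage computations.
    """
    nights: dict[date, SleepSession] = {}
    for s in sessions:
        cur = nights.get(s.wake_date)
        if cur is None or s.elapsed_minutes > cur.elapsed_minutes:
            nights[s.wake_date] = s
    return nights


@dataclass
class ChronoProfile:
    """Per-participant chronotype and sleep-need summary (times in hours)."""

    participant_id: str
    msf_uc: float
    msf: float
    sleep_need: float  # minutes
    n_work: int
    n_free: int
    mean_dur_work: float  # minutes (0 when no work nights)
    mean_dur_free: float  # minutes


def sleep_need(sessions: list[SleepSession]) -> float:
    """Individual sleep need SN: the mean nightly duration in minutes.

    The work/free weighted form (N_w*SD_w + N_f*SD_f)/(N_w+N_f) reduces to
    the plain mean over all nights because the weights are the day counts.
    """
    nights = nightly_sessions(sessions)
    if not nights:
        raise ValueError("no recorded nights")
    return float(np.mean([s.duration_minutes for s in nights.values()]))


def chronotype_msf(
    sessions: list[SleepSession],
    schedule: Schedule,
    mean_method: str = "circular",
) -> ChronoProfile:
    """Chronotype profile from nightly sleep and the work/free schedule.

    A night is a free-day night when its wake date is labelled free.
    Raises when there are no free-day nights (chronotype undefined).
    """
    nights = nightly_sessions(sessions)
    if not nights:
        raise ValueError("no recorded nights")
    free = [s for d, s in nights.items() if schedule.is_free(d)]
    work = [s for d, s in nights.items() if not schedule.is_free(d)]
    if not free:
        raise ValueError("chronotype undefined: no free-day nights")
    mean_fn = circular_mean_hours if mean_method == "circular" else linear_mean_hours
    msf_uc = mean_fn([s.mid_sleep_hours for s in free])
    sd_f = float(np.mean([s.duration_minutes for s in free]))
    sd_w = float(np.mean([s.duration_minutes for s in work])) if work else 0.0
    n_f, n_w = len(free), len(work)
    sn = (n_w * sd_w + n_f * sd_f) / (n_w + n_f)
    msf = (msf_uc - 0.5 * (sd_f - sn) / 60.0) % 24.0
    return ChronoProfile(
        participant_id=schedule.participant_id,
        msf_uc=msf_uc,
        msf=msf,
        sleep_need=sn,
        n_work=n_w,
        n_free=n_f,
        mean_dur_work=sd_w,
        mean_dur_free=sd_f,
    )


def internal_time(ext: datetime | float, msf: float) -> float:
    """Internal time InT = ExT - MSF, wrapped to [0, 24) hours."""
    from .records import clock_hours

    ext_h = clock_hours(ext) if isinstance(ext, datetime) else float(ext)
    return (ext_h - msf) % 24.0


def msf_instant(wake_date: date, msf: float) -> datetime:
    """The MSF clock time placed on the night that ends on ``wake_date``.

    Morning MSF values (before noon) fall on the wake date itself; evening
    values on the previous calendar date. This anchoring lets sleep shift
    exceed +/-12 h for heavily displaced (e.g. rotating-shift) sleep.
    """
    msf = msf % 24.0
    anchor = wake_date if msf < 12.0 else wake_date - timedelta(days=1)
    return combine_clock(anchor, msf)


def sleep_shift(session: SleepSession, profile: ChronoProfile) -> float:
    """Signed sleep shift in minutes: actual mid-sleep minus the MSF instant.

    Positive = slept later than the individual's chronotype.
    """
    expected = msf_instant(session.wake_date, profile.msf)
    return (session.mid_sleep - expected).total_seconds() / 60.0


def sleep_debt(duration_minutes: float, sn: float) -> float:
    """Nightly sleep debt: 1 - duration/SN (dimensionless; 0 = exactly SN)."""
    return 1.0 - duration_minutes / sn


def sleep_need_and_debt(sessions: list[SleepSession]) -> tuple[float, dict[date, float]]:
    """SN plus per-night debt keyed by wake date; debts average to zero."""
    nights = nightly_sessions(sessions)
    sn = sleep_need(sessions)
    return sn, {d: sleep_debt(s.duration_minutes, sn) for d, s in nights.items()}


@dataclass
class NightMetrics:
    """Derived metrics for one night (the longest session of its wake date)."""

    participant_id: str
    wake_date: date
    start: datetime
    end: datetime
    duration: float  # minutes
    rem_minutes: float | None
    light_minutes: float | None
    deep_minutes: float | None
    rem_pct: float | None
    light_pct: float | None
    deep_pct: float | None
    sleep_debt: float
    sleep_shift: float  # minutes
    sleep_end: float  # clock hours
    efficiency: float | None
    awakenings: int | None


def night_metrics(
    sessions: list[SleepSession],
    profile: ChronoProfile,
    sn: float | None = None,
) -> list[NightMetrics]:
    """NightMetrics for every recorded night, sorted by wake date.

    Stage percentages use the session's total duration as denominator and
    are reported only for staged nights (> 3 h with a stage breakdown).
    """
    nights = nightly_sessions(sessions)
    if sn is None:
        sn = sleep_need(sessions)
    out = []
    for d in sorted(nights):
        s = nights[d]
        stages = s.stage_minutes if s.has_stages else None

        def _stage(st):
            return None if stages is None or st not in stages else float(stages[st])

        def _pct(st):
            v = _stage(st)
            return None if v is None else 100.0 * v / s.duration_minutes

        out.append(
            NightMetrics(
                participant_id=s.participant_id,
                wake_date=d,
                start=s.start,
                end=s.end,
                duration=s.duration_minutes,
                rem_minutes=_stage("rem"),
                light_minutes=_stage("light"),
                deep_minutes=_stage("deep"),
                rem_pct=_pct("rem"),
                light_pct=_pct("light"),
                deep_pct=_pct("deep"),
                sleep_debt=sleep_debt(s.duration_minutes, sn),
                sleep_shift=sleep_shift(s, profile),
                sleep_end=s.sleep_end_hours,
                efficiency=s.efficiency,
                awakenings=s.awakenings_gt5min,
            )
        )
    return out


@dataclass
class WeeklyAggregate:
    """Means over the 7 calendar nights preceding a date, with imputation."""

    participant_id: str
    date: date
    duration: float
    rem_minutes: float | None
    light_minutes: float | None
    deep_minutes: float | None
    sleep_debt: float
    sleep_shift: float
    imputed_nights: int


def _running_mean_impute(values_by_date: dict[date, float], window: list[date]) -> tuple[list[float], int]:
    """Values for each window date, imputing gaps with the running mean of
    all recorded values strictly before that date (falling back to the
    overall recorded mean when a gap precedes every record)."""
    recorded = sorted(values_by_date)
    all_vals = [values_by_date[d] for d in recorded]
    out, imputed = [], 0
    for d in window:
        if d in values_by_date:
            out.append(values_by_date[d])
        else:
            prior = [values_by_date[r] for r in recorded if r < d]
            out.append(float(np.mean(prior)) if prior else float(np.mean(all_vals)))
            imputed += 1
    return out, imputed


def weekly_aggregates(
    nights: list[NightMetrics], as_of_date: date, epoch_days: int = 7
) -> WeeklyAggregate | None:
    """Mean sleep metrics over the 7 nights ending the night before a date.

    Window = wake dates ``as_of_date - 7 .. as_of_date - 1``. Missing nights
    are imputed per metric with the running mean of all recorded nights
    strictly before the gap. Returns None when no night precedes the date.
    """
    by_date = {n.wake_date: n for n in nights}
    prior_dates = [d for d in by_date if d < as_of_date]
    if not prior_dates:
        return None
    window = [as_of_date - timedelta(days=k) for k in range(epoch_days, 0, -1)]

    def _agg(getter):
        vals = {d: getter(by_date[d]) for d in prior_dates if getter(by_date[d]) is not None}
        if not vals:
            return None, 0
        series, imputed = _running_mean_impute(vals, window)
        return float(np.mean(series)), imputed

    duration, imputed = _agg(lambda n: n.duration)
    rem, _ = _agg(lambda n: n.rem_minutes)
    light, _ = _agg(lambda n: n.light_minutes)
    deep, _ = _agg(lambda n: n.deep_minutes)
    debt, _ = _agg(lambda n: n.sleep_debt)
    shift, _ = _agg(lambda n: n.sleep_shift)
    return WeeklyAggregate(
        participant_id=nights[0].participant_id,
        date=as_of_date,
        duration=duration,
        rem_minutes=rem,
        light_minutes=light,
        deep_minutes=deep,
        sleep_debt=debt,
        sleep_shift=shift,
        imputed_nights=imputed,
    )


def link_previous_sleep(
    task_timestamp: datetime,
    nights: list[NightMetrics],
    horizon_hours: float = LINK_HORIZON_HOURS,
) -> NightMetrics | None:
    """Most recent night ending before the task and within the horizon."""
    ends = [n.end for n in nights]
    if ends != sorted(ends):
        nights = sorted(nights, key=lambda n: n.end)
        ends = [n.end for n in nights]
    i = bisect_left(ends, task_timestamp) - 1
    if i < 0:
        return None
    night = nights[i]
    if (task_timestamp - night.end) > timedelta(hours=horizon_hours):
        return None
    return night


def time_since_wake(task_timestamp: datetime, nights: list[NightMetrics]) -> float | None:
    """Minutes since waking from the linked previous night, or None."""
    night = link_previous_sleep(task_timestamp, nights)
    if night is None:
        return None
    return (task_timestamp - night.end).total_seconds() / 60.0
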