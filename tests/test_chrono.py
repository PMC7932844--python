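"""Chronotype, sleep need/debt, sleep shift, weekly aggregates, linkage."""

from datetime import date, datetime, timedelta

import numpy as np
import pytest

from chronoperf import chrono
from chronoperf.records import Schedule, SleepSession
from conftest import make_night, week_schedule

MON = date(2019, 3, 4)


def _profile_sessions(pid="A"):
    """3 weeks: work nights 420 min ending ~07:00; free nights 540 min with
    mid-sleep exactly 05:00."""
    sessions = []
    for week in range(3):
        for dow in range(7):
            d = MON + timedelta(days=7 * week + dow + 1)
            if d.weekday() < 5:  # work night: wake on a weekday
                end = datetime(d.year, d.month, d.day, 7, 0)
                sessions.append(SleepSession(pid, end - timedelta(minutes=420), end))
            else:  # free night: mid-sleep 05:00, duration 540
                mid = datetime(d.year, d.month, d.day, 5, 0)
                sessions.append(SleepSession(pid, mid - timedelta(minutes=270), mid + timedelta(minutes=270)))
    return sessions


class TestMidSleep:
    def test_simple_midpoint(self):
        s = SleepSession("A", datetime(2019, 3, 4, 23, 0), datetime(2019, 3, 5, 7, 0))
        assert s.mid_sleep_hours == pytest.approx(3.0)

    def test_no_midnight_crossing(self):
        s = SleepSession("A", datetime(2019, 3, 5, 1, 0), datetime(2019, 3, 5, 9, 0))
        assert s.mid_sleep_hours == pytest.approx(5.0)

    def test_translation_equivariance_on_circle(self):
        a = SleepSession("A", datetime(2019, 3, 4, 22, 0), datetime(2019, 3, 5, 6, 0))
        b = SleepSession("A", datetime(2019, 3, 5, 2, 0), datetime(2019, 3, 5, 10, 0))
        assert (b.mid_sleep_hours - a.mid_sleep_hours) % 24 == pytest.approx(4.0)


class TestChronotype:
    def test_msf_formula_value(self):
        sessions = _profile_sessions()
        prof = chrono.chronotype_msf(sessions, week_schedule("A", MON))
        sn = (15 * 420 + 6 * 540) / 21
        assert prof.sleep_need == pytest.approx(sn)
        assert prof.msf_uc == pytest.approx(5.0)
        assert prof.msf == pytest.approx(5.0 - 0.5 * (540 - sn) / 60.0)

    def test_correction_vanishes_when_durations_equal(self):
        sessions = []
        for dow in range(14):
            d = MON + timedelta(days=dow + 1)
            end = datetime(d.year, d.month, d.day, 7, 0)
            sessions.append(SleepSession("A", end - timedelta(minutes=450), end))
        prof = chrono.chronotype_msf(sessions, week_schedule("A", MON))
        assert prof.msf == pytest.approx(prof.msf_uc)

    def test_free_day_oversleep_shifts_msf_earlier(self):
        prof = chrono.chronotype_msf(_profile_sessions(), week_schedule("A", MON))
        assert prof.msf < prof.msf_uc

    def test_no_free_nights_errors(self):
        d = MON
        sessions = [make_night("A", datetime(d.year, d.month, d.day, 23, 0), 450)]
        sch = Schedule("A", {d: "work", d + timedelta(days=1): "work"})
        with pytest.raises(ValueError, match="chronotype undefined"):
            chrono.chronotype_msf(sessions, sch)

    def test_translation_equivariance(self):
        sessions = _profile_sessions()
        shifted = [SleepSession(s.participant_id, s.start + timedelta(hours=2),
                                s.end + timedelta(hours=2)) for s in sessions]
        sch = week_schedule("A", MON)
        p0 = chrono.chronotype_msf(sessions, sch)
        p1 = chrono.chronotype_msf(shifted, sch)
        assert (p1.msf_uc - p0.msf_uc) % 24 == pytest.approx(2.0)
        assert (p1.msf - p0.msf) % 24 == pytest.approx(2.0)
        n0 = chrono.night_metrics(sessions, p0)
        n1 = chrono.night_metrics(shifted, p1)
        for a, b in zip(n0, n1):
            assert b.sleep_shift == pytest.approx(a.sleep_shift, abs=1e-9)


class TestInternalTime:
    def test_table_consistent_value(self):
        # clock 15:34 under a 04:01 chronotype is internal time 11:33
        assert chrono.internal_time(15 + 34 / 60, 4 + 1 / 60) == pytest.approx(11 + 33 / 60)

    def test_zero_at_msf(self):
        assert chrono.internal_time(5.0, 5.0) == 0.0

    def test_wraps(self):
        assert chrono.internal_time(2.0, 5.0) == pytest.approx(21.0)


class TestSleepShift:
    def _profile(self):
        return chrono.ChronoProfile("A", 4.0, 4.0, 450.0, 15, 6, 440.0, 470.0)

    def test_zero_when_at_msf(self):
        s = SleepSession("A", datetime(2019, 3, 5, 0, 0), datetime(2019, 3, 5, 8, 0))
        assert chrono.sleep_shift(s, self._profile()) == pytest.approx(0.0)

    def test_half_hour_late(self):
        s = SleepSession("A", datetime(2019, 3, 5, 0, 30), datetime(2019, 3, 5, 8, 30))
        assert chrono.sleep_shift(s, self._profile()) == pytest.approx(30.0)

    def test_hour_early(self):
        s = SleepSession("A", datetime(2019, 3, 4, 23, 0), datetime(2019, 3, 5, 7, 0))
        assert chrono.sleep_shift(s, self._profile()) == pytest.approx(-60.0)

    def test_shift_worker_daytime_sleep_exceeds_12h(self):
        # slept 09:00-19:00 after a night shift: mid-sleep 14:00, 10 h past a
        # 04:00 chronotype -- anchored to the wake date, so a heavily
        # displaced schedule can exceed +/-12 h rather than wrap.
        s = SleepSession("A", datetime(2019, 3, 5, 9, 0), datetime(2019, 3, 5, 19, 0))
        assert chrono.sleep_shift(s, self._profile()) == pytest.approx(600.0)


class TestSleepNeedAndDebt:
    def test_debt_zero_at_need(self):
        assert chrono.sleep_debt(450.0, 450.0) == 0.0

    def test_debt_half_at_half_need(self):
        assert chrono.sleep_debt(225.0, 450.0) == 0.5

    def test_weighted_example_and_zero_mean(self):
        sessions = []
        for k in range(5):
            d = MON + timedelta(days=k + 1)
            end = datetime(d.year, d.month, d.day, 7, 0)
            sessions.append(SleepSession("A", end - timedelta(minutes=420), end))
        for k in range(2):
            d = MON + timedelta(days=5 + k + 1)
            end = datetime(d.year, d.month, d.day, 9, 0)
            sessions.append(SleepSession("A", end - timedelta(minutes=540), end))
        sn, debts = chrono.sleep_need_and_debt(sessions)
        assert sn == pytest.approx((5 * 420 + 2 * 540) / 7)
        assert debts[date(2019, 3, 5)] == pytest.approx(1 - 420 / sn)
        assert debts[date(2019, 3, 10)] == pytest.approx(1 - 540 / sn)
        assert np.mean(list(debts.values())) == pytest.approx(0.0, abs=1e-12)

    def test_debt_mean_identically_zero_random(self):
        rng = np.random.default_rng(11)
        sessions = []
        for k in range(30):
            d = MON + timedelta(days=k + 1)
            end = datetime(d.year, d.month, d.day, 7, 0)
            sessions.append(SleepSession("A", end - timedelta(minutes=float(rng.uniform(200, 600))), end))
        _, debts = chrono.sleep_need_and_debt(sessions)
        assert np.mean(list(debts.values())) == pytest.approx(0.0, abs=1e-12)


def _nights(durations_by_offset, pid="A", profile=None):
    sessions = []
    for off, dur in durations_by_offset.items():
        d = MON + timedelta(days=off)
        end = datetime(d.year, d.month, d.day, 7, 0)
        sessions.append(SleepSession(pid, end - timedelta(minutes=dur), end))
    profile = profile or chrono.ChronoProfile(pid, 3.0, 3.0, 450.0, 5, 2, 430, 470)
    return chrono.night_metrics(sessions, profile)


class TestWeeklyAggregates:
    def test_full_week_plain_mean(self):
        nights = _nights({k: 420 for k in range(1, 8)})
        agg = chrono.weekly_aggregates(nights, MON + timedelta(days=8))
        assert agg.duration == pytest.approx(420.0)
        assert agg.imputed_nights == 0

    def test_single_gap_mean_preserving(self):
        offsets = {k: 420 for k in range(1, 8) if k != 4}
        agg = chrono.weekly_aggregates(_nights(offsets), MON + timedelta(days=8))
        assert agg.duration == pytest.approx(420.0)
        assert agg.imputed_nights == 1

    def test_running_mean_imputation_value(self):
        # nights {400, 440, missing}: the gap is imputed with mean(400, 440) = 420
        nights = _nights({1: 400, 2: 440})
        agg = chrono.weekly_aggregates(nights, MON + timedelta(days=4), epoch_days=3)
        assert agg.imputed_nights == 1
        assert agg.duration == pytest.approx(420.0)

    def test_no_prior_nights_gives_missing(self):
        nights = _nights({5: 420})
        assert chrono.weekly_aggregates(nights, MON + timedelta(days=3)) is None


class TestLinkage:
    def test_same_day_link(self):
        nights = _nights({1: 480})
        task_ts = datetime(2019, 3, 5, 14, 0)
        night = chrono.link_previous_sleep(task_ts, nights)
        assert night is not None and night.wake_date == date(2019, 3, 5)
        assert chrono.time_since_wake(task_ts, nights) == pytest.approx(420.0)

    def test_most_recent_wins(self):
        nights = _nights({1: 480, 2: 480})
        night = chrono.link_previous_sleep(datetime(2019, 3, 6, 9, 0), nights)
        assert night.wake_date == date(2019, 3, 6)

    def test_horizon_excludes_stale(self):
        nights = _nights({1: 480})
        assert chrono.link_previous_sleep(datetime(2019, 3, 8, 12, 0), nights) is None

    def test_task_before_any_wake_is_missing(self):
        nights = _nights({3: 480})
        assert chrono.time_since_wake(datetime(2019, 3, 5, 9, 0), nights) is None

    def test_one_minute_after_wake(self):
        nights = _nights({1: 480})
        assert chrono.time_since_wake(datetime(2019, 3, 5, 7, 1), nights) == pytest.approx(1.0)
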