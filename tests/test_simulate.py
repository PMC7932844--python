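"""Synthetic cohort generator: determinism, constraints and calibration."""

import dataclasses
from datetime import timedelta

import numpy as np
import pytest

from chronoperf import io as cio
from chronoperf.simulate import (
    Couplings,
    HomeostatTrajectory,
    SimConfig,
    circadian_value,
    homeostatic_decay,
    homeostatic_value,
    simulate_cohort,
    simulate_sleep_schedule,
)
from chronoperf.records import combine_clock
from conftest import small_config


def degenerate_config(**overrides):
    """All couplings, rhythm amplitudes, noise and spreads set to zero."""
    base = dict(
        n_regular=2, n_shift=1, n_student=1, days=14,
        couplings=Couplings().zeroed(),
        circadian_amplitude_alertness=0.0, circadian_amplitude_throughput=0.0,
        alertness_noise_sd=0.0, throughput_noise_sd=0.0,
        participant_mrt_log_sd=0.0, participant_naa_sd=0.0,
        pvt_rt_spread=0.0, false_start_prob=0.0,
        include_streams=False,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestProcessModels:
    def test_circadian_peak_at_offset(self):
        t = combine_clock(SimConfig().start_date, (4.0 + 13.5) % 24.0)
        assert circadian_value(t, 4.0, 13.5, 2.5) == pytest.approx(2.5)

    def test_circadian_trough_half_period_later(self):
        t = combine_clock(SimConfig().start_date, (4.0 + 13.5 + 12.0) % 24.0)
        assert circadian_value(t, 4.0, 13.5, 2.5) == pytest.approx(-2.5)

    def test_zero_amplitude_is_flat(self):
        t = combine_clock(SimConfig().start_date, 9.0)
        assert circadian_value(t, 4.0, 13.5, 0.0) == 0.0

    def test_homeostatic_boundaries_and_monotonicity(self):
        assert homeostatic_value(0.0, s0=0.0) == 0.0
        assert homeostatic_value(1e9, s0=0.0) == pytest.approx(1.0)
        hs = [homeostatic_value(m, s0=0.2) for m in range(0, 1200, 60)]
        assert all(b > a for a, b in zip(hs, hs[1:]))

    def test_decay_releases_pressure(self):
        assert homeostatic_decay(0.0, s0=0.8) == 0.8
        assert homeostatic_decay(1e9, s0=0.8) == pytest.approx(0.0)

    def test_trajectory_continuous_across_transitions(self):
        cfg = SimConfig()
        rng = np.random.default_rng(0)
        nights, _, _ = simulate_sleep_schedule("regular", 10, rng, cfg)
        traj = HomeostatTrajectory([(s.start, s.end) for s in nights])
        for s in nights:
            for edge in (s.start, s.end):
                before = traj.value(edge - timedelta(seconds=30))
                after = traj.value(edge + timedelta(seconds=30))
                assert abs(after - before) < 0.01


class TestSleepSchedules:
    def test_seeded_determinism(self):
        a, _, _ = simulate_sleep_schedule("student", 14, np.random.default_rng(3))
        b, _, _ = simulate_sleep_schedule("student", 14, np.random.default_rng(3))
        assert a == b

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            simulate_sleep_schedule("regular", 5, np.random.default_rng(0))

    def test_schedule_labels_cover_all_wake_dates(self):
        nights, schedule, _ = simulate_sleep_schedule("shift", 21, np.random.default_rng(1))
        assert schedule.covers(s.wake_date for s in nights)

    def test_shift_group_has_larger_sleep_shift_spread(self):
        from chronoperf import chrono

        for seed in (0, 1, 2):
            spreads = {}
            for group in ("regular", "shift"):
                rng = np.random.default_rng(seed)
                nights, schedule, _ = simulate_sleep_schedule(group, 42, rng)
                prof = chrono.chronotype_msf(nights, schedule)
                shifts = [n.sleep_shift for n in chrono.night_metrics(nights, prof)]
                spreads[group] = np.std(shifts)
            assert spreads["shift"] > spreads["regular"]

    def test_nights_never_overlap(self):
        for group in ("regular", "shift", "student"):
            nights, _, _ = simulate_sleep_schedule(group, 42, np.random.default_rng(9))
            ordered = sorted(nights, key=lambda s: s.start)
            for a, b in zip(ordered, ordered[1:]):
                assert b.start >= a.end


class TestCohort:
    def test_bit_reproducibility_on_disk(self, tmp_path):
        cfg = small_config(days=10)
        for sub in ("a", "b"):
            simulate_cohort(cfg, seed=5).to_files(tmp_path / sub)
        for name in ("tasks.jsonl", "sleep.csv", "schedule.csv", "minutes.csv", "truth_tasks.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_degenerate_constants_give_flat_outcomes(self):
        cohort = simulate_cohort(degenerate_config(), seed=2)
        cfg = degenerate_config()
        for task in cohort.tasks:
            rts = {r.response_time_ms for r in task.pvt_responses}
            assert rts == {round(cfg.base_mrt_ms, 1)}
            assert task.add_attempts == round(cfg.base_naa)

    def test_minimum_gap_between_tasks(self, small_cohort):
        by_pid = {}
        for t in small_cohort.tasks:
            by_pid.setdefault(t.participant_id, []).append(t.timestamp)
        for times in by_pid.values():
            gaps = np.diff([t.timestamp() for t in sorted(times)]) / 60.0
            assert (gaps >= small_cohort.config.min_gap_minutes).all()

    def test_round_trip_through_io_layer(self, small_cohort, small_cohort_dir):
        tasks = cio.read_task_sessions(small_cohort_dir / "tasks.jsonl")
        sleep = cio.read_sleep_sessions(small_cohort_dir / "sleep.csv")
        assert tasks == sorted(small_cohort.tasks)
        key = lambda s: (s.participant_id, s.start)  # noqa: E731
        assert sorted(sleep, key=key) == sorted(small_cohort.sleep, key=key)

    def test_truth_is_aligned_with_tasks(self, small_cohort):
        assert len(small_cohort.truth.tasks) == len(small_cohort.tasks)
        assert set(small_cohort.truth.participants["participant_id"]) == set(
            small_cohort.schedules
        )


class TestStreams:
    def test_no_steps_during_sleep(self, small_cohort):
        pid = next(iter(small_cohort.streams))
        stream = small_cohort.streams[pid]
        nights = [s for s in small_cohort.sleep if s.participant_id == pid]
        for s in nights[:10]:
            sel = stream.frame.loc[s.start: s.end - timedelta(minutes=1), "steps"]
            assert (sel == 0).all()

    def test_waking_heart_rate_near_configured_level(self, small_cohort):
        cfg = small_cohort.config
        truth = small_cohort.truth.participants.set_index("participant_id")
        for pid, stream in small_cohort.streams.items():
            nights = [s for s in small_cohort.sleep if s.participant_id == pid]
            asleep = np.zeros(len(stream.frame), dtype=bool)
            idx = stream.frame.index
            for s in nights:
                asleep |= (idx >= s.start) & (idx < s.end)
            waking_mean = stream.frame.loc[~asleep, "heart_rate"].mean()
            expected = truth.loc[pid, "resting_hr"] + cfg.hr_wake_offset
            assert waking_mean == pytest.approx(expected, abs=2.0)

    def test_opt_in_stream_gaps(self):
        cfg = small_config(days=10, stream_missing_rate=0.1)
        cohort = simulate_cohort(cfg, seed=3)
        frac = np.mean([s.frame["heart_rate"].isna().mean() for s in cohort.streams.values()])
        assert 0.05 < frac < 0.15

    def test_calibration_moments_fields(self, small_cohort):
        cfg_fields = {f.name for f in dataclasses.fields(SimConfig)}
        assert {"tasks_per_day", "min_gap_minutes", "acrophase_offset_hours"} <= cfg_fields
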