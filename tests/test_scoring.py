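"""Session/daily scoring: medians, retention filters and relative scores."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronoperf import scoring
from conftest import make_task, make_tasks_from_mrts


class TestMedianResponseTime:
    def test_odd_count_median(self):
        t = make_task("A", datetime(2019, 3, 5, 9), [300, 350, 400])
        assert scoring.median_response_time(t) == 350

    def test_false_starts_ignored(self):
        t = make_task("A", datetime(2019, 3, 5, 9), [300, 350, 400], false_starts=[100])
        assert scoring.median_response_time(t) == 350

    def test_single_response(self):
        t = make_task("A", datetime(2019, 3, 5, 9), [234.0])
        assert scoring.median_response_time(t) == 234.0

    def test_even_count_is_midpoint(self):
        t = make_task("A", datetime(2019, 3, 5, 9), [300, 400])
        assert scoring.median_response_time(t) == 350

    def test_no_valid_stimuli_is_missing(self):
        t = make_task("A", datetime(2019, 3, 5, 9), [], false_starts=[100])
        assert scoring.median_response_time(t) is None


class TestPvtFilter:
    def test_filter_order_hand_trace(self):
        # first instance (400) dropped, 850 dropped by the 800 ms threshold,
        # 420/430 survive the 3-SD step.
        tasks = make_tasks_from_mrts("A", [400, 850, 420, 430])
        flags = scoring.filter_pvt_sessions(tasks)
        assert flags == [False, False, True, True]

    def test_zero_variance_keeps_all_survivors(self):
        tasks = make_tasks_from_mrts("A", [500] * 100)
        flags = scoring.filter_pvt_sessions(tasks)
        assert flags == [False] + [True] * 99

    def test_exactly_800_ms_is_retained(self):
        tasks = make_tasks_from_mrts("A", [400, 800, 800, 800])
        flags = scoring.filter_pvt_sessions(tasks)
        assert flags == [False, True, True, True]

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(0)
        tasks = make_tasks_from_mrts("A", rng.normal(400, 120, size=60).clip(150, 1200))
        flags = scoring.filter_pvt_sessions(tasks)
        survivors = [t for t, f in zip(tasks, flags) if f]
        # re-filtering the survivors, minus the first-instance rule which has
        # already been applied, changes nothing
        reflagged = scoring.filter_pvt_sessions(survivors)
        assert all(reflagged[1:])

    def test_retained_sessions_satisfy_threshold(self):
        rng = np.random.default_rng(1)
        tasks = make_tasks_from_mrts("A", rng.normal(500, 250, size=80).clip(100, 2000))
        flags = scoring.filter_pvt_sessions(tasks)
        for t, f in zip(tasks, flags):
            if f:
                assert scoring.median_response_time(t) <= 800

    def test_add_outlier_dropped_by_sd_rule(self):
        naas = [15] * 25 + [16] * 25
        tasks = make_tasks_from_mrts("A", [400] * 51, naas=[15] + naas)
        # inject an outlier at mean + ~4 SD of the surviving set
        tasks.append(make_task("A", tasks[-1].timestamp + timedelta(hours=3), [400], naa=18))
        flags = scoring.filter_add_sessions(tasks)
        assert flags[-1] == False  # noqa: E712
        assert sum(flags) == 50  # 52 batteries minus first instance minus outlier


class TestRelativeScores:
    def test_rrt_formula(self):
        tasks = make_tasks_from_mrts("A", [400, 300, 500])
        scores = scoring.score_sessions(tasks)
        assert scores[0].rrt is None  # first instance
        assert scores[1].rrt == pytest.approx(25.0)
        assert scores[2].rrt == pytest.approx(-25.0)

    def test_raa_formula(self):
        tasks = make_tasks_from_mrts("A", [400, 400, 400], naas=[10, 15, 25])
        scores = scoring.score_sessions(tasks)
        assert scores[1].raa == pytest.approx(-25.0)
        assert scores[2].raa == pytest.approx(25.0)

    def test_all_equal_gives_zero(self):
        tasks = make_tasks_from_mrts("A", [400] * 6, naas=[18] * 6)
        scores = scoring.score_sessions(tasks)
        assert all(s.rrt == pytest.approx(0.0) for s in scores[1:])
        assert all(s.raa == pytest.approx(0.0) for s in scores[1:])

    def test_sign_contract(self):
        rng = np.random.default_rng(3)
        mrts = rng.uniform(250, 700, size=40)
        naas = rng.integers(8, 30, size=40)
        scores = scoring.score_sessions(make_tasks_from_mrts("A", mrts, naas=list(naas)))
        kept = [s for s in scores if s.retained_pvt]
        for a in kept:
            for b in kept:
                if a.mrt < b.mrt:
                    assert a.rrt > b.rrt
        kept = [s for s in scores if s.retained_add]
        for a in kept:
            for b in kept:
                if a.naa < b.naa:
                    assert a.raa < b.raa

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=150, max_value=800), min_size=3, max_size=40))
    def test_participant_mean_relative_scores_are_zero(self, mrts):
        scores = scoring.score_sessions(make_tasks_from_mrts("A", mrts))
        rrts = [s.rrt for s in scores if s.retained_pvt]
        if rrts:
            assert np.mean(rrts) == pytest.approx(0.0, abs=1e-9)


class TestInclusion:
    def _cohort(self, counts):
        tasks = []
        for pid, n in counts.items():
            tasks.extend(make_tasks_from_mrts(pid, [400] * n))
        return tasks

    def test_boundary_inclusive_at_threshold(self):
        kept = scoring.include_participants(self._cohort({"A": 50, "B": 41, "C": 42}))
        assert kept == {"A", "C"}

    def test_all_qualify_is_identity(self):
        kept = scoring.include_participants(self._cohort({"A": 42, "B": 45}))
        assert kept == {"A", "B"}

    def test_empty_cohort_after_filter_errors(self):
        with pytest.raises(ValueError):
            scoring.include_participants(self._cohort({"A": 10, "B": 5}))


class TestDailyScores:
    def test_daily_median(self):
        start = datetime(2019, 3, 5, 9)
        tasks = [
            make_task("A", start, [999]),  # first instance, dropped
            make_task("A", start + timedelta(hours=2), [300]),
            make_task("A", start + timedelta(hours=5), [400]),
        ]
        daily = scoring.daily_relative_scores(scoring.score_sessions(tasks))
        assert daily["daily_median_mrt"].iloc[0] == pytest.approx(350.0)

    def test_relative_daily_scores_from_medians(self):
        start = datetime(2019, 3, 5, 9)
        tasks = [make_task("A", start, [999])]
        tasks += [make_task("A", start + timedelta(hours=3), [350])]
        tasks += [make_task("A", start + timedelta(days=1), [450])]
        daily = scoring.daily_relative_scores(scoring.score_sessions(tasks))
        # daily medians {350, 450}: baseline 400 -> +/- 12.5%
        assert daily["relative_daily_rrt"].tolist() == pytest.approx([12.5, -12.5])

    def test_mean_relative_daily_score_is_zero(self):
        rng = np.random.default_rng(4)
        start = datetime(2019, 3, 5, 8)
        tasks = []
        for day in range(14):
            for k in range(3):
                tasks.append(
                    make_task("A", start + timedelta(days=day, hours=3 * k),
                              [float(rng.uniform(250, 650))], naa=int(rng.integers(8, 28)))
                )
        daily = scoring.daily_relative_scores(scoring.score_sessions(tasks))
        assert daily["relative_daily_rrt"].mean() == pytest.approx(0.0, abs=1e-9)
        assert daily["relative_daily_raa"].mean() == pytest.approx(0.0, abs=1e-9)
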