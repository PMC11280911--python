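"""Quality filters (in their fixed order) and 10-day grouping."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from dfapower.cohort import (
    FilterConfig,
    FilteredWorkout,
    build_groups,
    filter_workout,
)
from dfapower.dfa_windows import WindowSample
from dfapower.preprocess import PreprocessReport


def sample(t_end, a1=0.8, p=200.0, valid=True):
    return WindowSample(t_end=t_end, a1=a1, p=p, n_beats=150, valid=valid)


def clean_report(n=1000, flagged=0):
    return PreprocessReport(n_beats=n, n_flagged=flagged)


def in_crop_samples(n, a1=0.8, p=200.0):
    return [sample(300.0 + 5 * i, a1=a1, p=p) for i in range(n)]


class TestFilterWorkout:
    def test_clean_workout_passes(self):
        pts, rep = filter_workout(in_crop_samples(100), clean_report())
        assert rep.passed and rep.reasons == ()
        assert pts.shape == (100, 2)

    def test_artifact_fraction_above_5_percent_rejected(self):
        pts, rep = filter_workout(in_crop_samples(50), clean_report(100, 6))
        assert not rep.passed
        assert "artifacts" in rep.reasons
        assert pts.shape[0] == 0

    def test_crop_keeps_minutes_5_to_20_only(self):
        samples = [sample(100.0), sample(299.0), sample(300.0), sample(1200.0), sample(1205.0)]
        pts, rep = filter_workout(samples, clean_report())
        # only the two in-crop samples survive, but too few checks fail
        assert rep.n_points_in == 5

    def test_pedaling_fraction_rule(self):
        # 20 cropped samples, 3 with p = 0 -> 17/20 = 0.85 < 0.90
        samples = in_crop_samples(17) + [
            sample(400.0 + i, p=0.0) for i in range(3)
        ]
        pts, rep = filter_workout(samples, clean_report())
        assert rep.pedaling_fraction == pytest.approx(0.85)
        assert "pedaling" in rep.reasons and not rep.passed

    def test_zero_power_points_discarded_after_pedaling_check(self):
        # 95 pedaling + 5 coasting: fraction 0.95 passes, p = 0 dropped
        samples = in_crop_samples(95) + [sample(800.0 + i, p=0.0) for i in range(5)]
        pts, rep = filter_workout(samples, clean_report())
        assert rep.passed
        assert pts.shape[0] == 95
        assert np.all(pts[:, 0] > 0)

    def test_dynamic_range_rule(self):
        # 100 samples, 60 with a1 >= 1.0 -> dynamic fraction 0.40 < 0.50
        samples = in_crop_samples(40, a1=0.8) + in_crop_samples(60, a1=1.3)
        pts, rep = filter_workout(samples, clean_report())
        assert rep.dynamic_fraction == pytest.approx(0.40)
        assert "dynamic_range" in rep.reasons and not rep.passed

    def test_filter_order_dynamic_fraction_after_discard(self):
        """Regression for the specified step order: the dynamic fraction
        is computed after zero-power samples are discarded, so coasting
        samples in the dynamic range cannot rescue an easy ride."""
        dyn_coasting = [sample(300.0 + i, a1=0.5, p=0.0) for i in range(2)]
        pedaling = [sample(400.0 + 5 * i, a1=0.6, p=180.0) for i in range(8)] + [
            sample(500.0 + 5 * i, a1=1.2, p=120.0) for i in range(10)
        ]
        pts, rep = filter_workout(dyn_coasting + pedaling, clean_report())
        assert rep.passed is False
        assert "pedaling" not in rep.reasons  # 18/20 = 0.90 passes step 3
        # pre-discard the dynamic share would be 10/20 = 0.50 (pass);
        # post-discard it is 8/18 = 0.44 (fail)
        assert rep.dynamic_fraction == pytest.approx(8 / 18)
        assert "dynamic_range" in rep.reasons

    def test_empty_after_crop(self):
        samples = [sample(150.0), sample(250.0)]
        pts, rep = filter_workout(samples, clean_report())
        assert rep.reasons == ("empty_after_crop",)

    def test_deterministic(self):
        samples = in_crop_samples(30)
        r1 = filter_workout(samples, clean_report())[1]
        r2 = filter_workout(samples, clean_report())[1]
        assert r1 == r2

    def test_retained_points_positive_power_finite_a1(self):
        samples = in_crop_samples(95) + [
            sample(310.0 + i, a1=float("nan"), valid=False) for i in range(5)
        ]
        pts, rep = filter_workout(samples, clean_report())
        assert np.all(pts[:, 0] > 0) and np.all(np.isfinite(pts[:, 1]))


def fw(user, day, wid=None):
    return FilteredWorkout(
        workout_id=wid or f"{user}-{day}",
        user_id=user,
        start_date=datetime(2024, 3, 1) + timedelta(days=day),
        points=np.array([[200.0, 0.8]]),
    )


class TestBuildGroups:
    def test_all_within_ten_days_single_group(self):
        groups = build_groups([fw("u", d) for d in (0, 2, 4, 6, 9)])
        assert len(groups) == 1
        assert len(groups[0].workout_ids) == 5

    def test_fewer_than_four_workouts_no_group(self):
        assert build_groups([fw("u", d) for d in (0, 3, 8)]) == []

    def test_tumbling_windows_disjoint(self):
        groups = build_groups([fw("u", d) for d in (0, 1, 2, 3, 15, 16, 17, 18)])
        assert len(groups) == 2
        assert all(len(g.workout_ids) == 4 for g in groups)
        ids = [i for g in groups for i in g.workout_ids]
        assert len(ids) == len(set(ids))  # no workout in two groups

    def test_group_span_never_exceeds_ten_days(self):
        groups = build_groups([fw("u", d) for d in (0, 1, 9, 10, 11, 12, 13)])
        for g in groups:
            assert g.end_date - g.start_date <= timedelta(days=10)

    def test_users_grouped_separately(self):
        ws = [fw("a", d) for d in range(4)] + [fw("b", d) for d in range(4)]
        groups = build_groups(ws)
        assert {g.user_id for g in groups} == {"a", "b"}

    def test_points_pooled_in_member_order(self):
        ws = [fw("u", d) for d in range(4)]
        groups = build_groups(ws)
        assert groups[0].points.shape == (4, 2)


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(max_artifact_fraction=1.5)
    with pytest.raises(ValueError):
        FilterConfig(crop_start_s=1300.0)
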