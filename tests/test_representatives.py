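"""Segmentation layouts, representative averaging, correlation variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfapower.representatives import (
    RepresentativePoint,
    correlation_size_class,
    correlations,
    make_representatives,
    segment,
)

from conftest import brute_spearman


def pts(pairs):
    return np.asarray(pairs, dtype=float)


def cloud(a1_values, p_values=None):
    a1_values = np.asarray(a1_values, dtype=float)
    if p_values is None:
        p_values = 400.0 - 250.0 * a1_values
    return np.column_stack([np.asarray(p_values, dtype=float), a1_values])


class TestSegment:
    def test_single_workout_capped_at_1_2(self):
        scheme = segment(cloud(np.linspace(0.4, 1.5, 50)), "single")
        assert scheme.a1_star == pytest.approx(1.2)
        assert scheme.edges_dynamic.size == 9  # 8 bins
        np.testing.assert_allclose(np.diff(scheme.edges_dynamic), 0.1)

    def test_single_workout_max_below_cap(self):
        scheme = segment(cloud(np.linspace(0.4, 0.9, 50)), "single")
        assert scheme.a1_star == pytest.approx(0.9)
        assert scheme.edges_dynamic[0] == pytest.approx(0.4)
        assert scheme.edges_dynamic[-1] == pytest.approx(0.9)

    def test_group_nine_plus_five_bins_capped_at_1_8(self):
        scheme = segment(cloud(np.linspace(0.55, 2.3, 200)), "group")
        assert scheme.a1_star == pytest.approx(1.8)
        assert scheme.edges_dynamic.size == 10  # 9 bins on [0.55, 1.0]
        np.testing.assert_allclose(np.diff(scheme.edges_dynamic), 0.05)
        assert scheme.edges_upper.size == 6  # 5 bins on [1.0, 1.8]
        np.testing.assert_allclose(np.diff(scheme.edges_upper), 0.16)

    def test_group_all_dynamic(self):
        scheme = segment(cloud(np.linspace(0.4, 0.95, 60)), "group")
        assert scheme.edges_upper.size == 0

    def test_degenerate_range_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            segment(cloud([0.8] * 10), "single")


class TestMakeRepresentatives:
    def test_bin_below_min_count_yields_nothing(self):
        points = cloud(np.linspace(0.4, 1.1, 7))  # 7 points over 8 bins
        scheme = segment(points, "single")
        assert make_representatives(points, scheme, 8) == []

    def test_constant_bin_mean_and_zero_sd(self):
        points = pts([[200.0, 0.8]] * 10 + [[100.0, 0.3]] * 10)
        scheme = segment(points, "single")
        reps = make_representatives(points, scheme, 8)
        top = max(reps, key=lambda r: r.a1_avg)
        assert (top.p_avg, top.a1_avg) == (200.0, 0.8)
        assert top.p_sd == 0.0 and top.a1_sd == 0.0

    def test_hand_computed_bin_average(self):
        """Twelve constructed points in one group-mode bin average to
        (200 W, 0.74)."""
        bin_pts = [[100.0, 0.70], [200.0, 0.74], [300.0, 0.78]] * 4
        # anchor point stretches the dynamic range to [0.05, 1.0] so the
        # bin [0.683, 0.789) holds all twelve points
        points = pts(bin_pts + [[390.0, 0.05]])
        scheme = segment(points, "group")
        reps = make_representatives(points, scheme, 10)
        assert len(reps) == 1
        assert reps[0].p_avg == pytest.approx(200.0)
        assert reps[0].a1_avg == pytest.approx(0.74)
        assert reps[0].n_points == 12

    def test_rep_count_caps(self, rng):
        single = cloud(rng.uniform(0.3, 1.3, 2000))
        reps_s = make_representatives(single, segment(single, "single"), 8)
        assert len(reps_s) <= 8
        group = cloud(rng.uniform(0.3, 2.0, 5000))
        reps_g = make_representatives(group, segment(group, "group"), 10)
        assert len(reps_g) <= 14

    def test_points_above_cap_ignored(self, rng):
        a1 = np.concatenate([rng.uniform(0.3, 1.0, 500), np.full(50, 2.5)])
        points = cloud(a1)
        scheme = segment(points, "group")
        reps = make_representatives(points, scheme, 10)
        assert all(r.a1_avg <= scheme.a1_star for r in reps)

    def test_representative_inside_its_bin(self, rng):
        points = cloud(rng.uniform(0.35, 1.15, 1000))
        scheme = segment(points, "single")
        for r in make_representatives(points, scheme, 8):
            assert scheme.a1_min - 1e-12 <= r.a1_avg <= scheme.a1_star + 1e-12

    def test_conservation_of_weighted_mean(self, rng):
        """When every bin is populated, the count-weighted mean of the
        representatives' p equals the overall mean p of in-range points."""
        a1 = rng.uniform(0.3, 1.19, 4000)
        points = cloud(a1, 400 - 250 * a1 + rng.normal(0, 10, a1.size))
        scheme = segment(points, "single")
        reps = make_representatives(points, scheme, 8)
        assert len(reps) == 8
        w_mean = sum(r.p_avg * r.n_points for r in reps) / sum(
            r.n_points for r in reps
        )
        in_range = points[points[:, 1] <= scheme.a1_star]
        assert w_mean == pytest.approx(in_range[:, 0].mean(), rel=1e-12)


def rep(a1, p, region="dynamic"):
    return RepresentativePoint(a1, p, 0.0, 0.0, 12, region)


class TestCorrelations:
    def test_perfect_monotone_reps_give_minus_one(self, rng):
        reps = [rep(0.4 + 0.1 * i, 400 - 50 * i) for i in range(6)]
        points = cloud(rng.uniform(0.3, 1.0, 30))
        out = correlations(points, reps, "single")
        assert out.r_representative_dynamic == pytest.approx(-1.0)

    def test_constant_power_reps_absent_with_tag(self, rng):
        reps = [rep(0.4 + 0.1 * i, 200.0) for i in range(5)]
        points = cloud(rng.uniform(0.3, 1.0, 30))
        out = correlations(points, reps, "single")
        assert out.r_representative_dynamic is None
        assert "r_representative_dynamic" in out.tags

    def test_fewer_than_three_reps_absent(self, rng):
        points = cloud(rng.uniform(0.3, 1.0, 30))
        out = correlations(points, [rep(0.5, 300), rep(0.7, 250)], "single")
        assert out.r_representative_dynamic is None
        assert out.tags["r_representative_dynamic"] == "insufficient_reps"

    def test_matches_brute_force_rank_computation(self, rng):
        for _ in range(20):
            points = cloud(rng.uniform(0.2, 1.5, 10), rng.uniform(50, 400, 10))
            out = correlations(points, [], "single")
            assert out.r_standard_total == pytest.approx(
                brute_spearman(points[:, 1], points[:, 0]), abs=1e-12
            )

    def test_dynamic_variant_restricted_below_cutoff(self, rng):
        a1 = np.concatenate([rng.uniform(0.3, 0.99, 40), rng.uniform(1.0, 1.6, 40)])
        points = cloud(a1, rng.uniform(100, 400, 80))
        out = correlations(points, [], "group")
        dyn = points[points[:, 1] < 1.0]
        assert out.r_standard_dynamic == pytest.approx(
            brute_spearman(dyn[:, 1], dyn[:, 0]), abs=1e-12
        )

    def test_representative_all_needs_upper_region(self, rng):
        points = cloud(rng.uniform(0.3, 1.5, 60))
        reps_dyn = [rep(0.4 + 0.1 * i, 400 - 40 * i) for i in range(5)]
        out = correlations(points, reps_dyn, "group")
        assert out.r_representative_all is None
        reps = reps_dyn + [rep(1.1, 150, "upper"), rep(1.3, 120, "upper")]
        out = correlations(points, reps, "group")
        assert out.r_representative_all == pytest.approx(-1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariance_under_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        points = cloud(r.uniform(0.2, 1.5, 15), r.uniform(50, 400, 15))
        base = correlations(points, [], "single").r_standard_total
        warped = np.column_stack([np.exp(points[:, 0] / 100.0), points[:, 1] ** 3])
        out = correlations(warped, [], "single").r_standard_total
        assert out == pytest.approx(base, abs=1e-12)


@pytest.mark.parametrize(
    "r,expected",
    [
        (0.95, "high"), (-0.85, "high"),
        (0.7, "moderate"), (-0.65, "moderate"),
        (0.4, "low"), (-0.31, "low"),
        (0.55, "unclassified"), (0.1, "unclassified"),
    ],
)
def test_size_classification_bands(r, expected):
    assert correlation_size_class(r) == expected
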