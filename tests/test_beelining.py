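"""Beelining: calibration, constraint building, triangulation, density."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beetracker import (
    Beeline,
    BeelineObservation,
    FeederStation,
    GeoPoint,
    LocalFrame,
    NestLocalizationModel,
    RangeDisc,
    UnlocalizableError,
    bearing_between,
    circular_mean,
    density_from_survey,
    destination_point,
    distance_between,
    fastest_bee,
    localize_nest,
    make_beeline,
    max_nest_distance,
    merge_nest_estimates,
    round_trip_for_distance,
    survey_area,
)
from _oracles import grid_search_ray_point, monte_carlo_union_area_km2


def obs(feeder="F1", bee=None, t=None, bearing=None):
    return BeelineObservation(feeder, bee, t, bearing)


class TestMaxNestDistance:
    @pytest.mark.parametrize("t, expected", [(3.0, 101.25), (5.0, 587.25)])
    def test_calibration_values(self, t, expected):
        assert max_nest_distance(t) == pytest.approx(expected)

    def test_root_reports_zero_with_warning(self):
        with pytest.warns(UserWarning, match="adjacent"):
            assert max_nest_distance(627.75 / 243.0) == 0.0

    def test_never_negative(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert max_nest_distance(1.0) == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(min_value=2.6, max_value=60.0))
    def test_affine_and_increasing(self, t):
        assert max_nest_distance(t + 0.5) - max_nest_distance(t) == pytest.approx(243.0 * 0.5)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(min_value=1.0, max_value=10_000.0))
    def test_inverse_round_trip(self, d):
        assert max_nest_distance(round_trip_for_distance(d)) == pytest.approx(d, abs=1e-9)


class TestFastestBee:
    def test_minimum_selected(self):
        bees = [obs(t=4.2), obs(t=3.1), obs(t=6.0)]
        assert fastest_bee(bees) is bees[1]

    def test_single_observation(self):
        o = obs(t=5.0)
        assert fastest_bee([o]) is o

    def test_tie_broken_by_first_occurrence(self):
        first, second = obs(bee="a", t=3.0), obs(bee="b", t=3.0)
        assert fastest_bee([first, second]) is first

    def test_untimed_rows_ignored_and_empty_errors(self):
        assert fastest_bee([obs(bearing=90.0), obs(t=4.0)]).round_trip_min == 4.0
        with pytest.raises(ValueError):
            fastest_bee([obs(bearing=90.0)])


class TestCircularMeanAndBeeline:
    def test_plain_mean(self):
        assert circular_mean([90.0, 100.0]) == pytest.approx(95.0)

    def test_wrap_aware_mean(self):
        assert circular_mean([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)

    def test_beeline_from_observations(self, hainich):
        feeder = FeederStation("F1", hainich)
        line = make_beeline(feeder, [obs(t=4.0, bearing=90.0), obs(t=5.0, bearing=100.0)])
        assert isinstance(line, Beeline)
        assert line.bearing == pytest.approx(95.0)
        assert line.max_distance == pytest.approx(243.0 * 4.0 - 627.75)  # 344.25

    def test_no_bearings_gives_range_disc(self, hainich):
        feeder = FeederStation("F1", hainich)
        disc = make_beeline(feeder, [obs(t=3.0)])
        assert isinstance(disc, RangeDisc)
        assert disc.radius == pytest.approx(101.25)

    def test_no_time_data_errors(self, hainich):
        with pytest.raises(ValueError):
            make_beeline(FeederStation("F1", hainich), [obs(bearing=10.0)])


class TestLocalization:
    def test_two_perpendicular_rays_cross_exactly(self, hainich):
        nest = destination_point(hainich, 0.0, 1000.0)
        o2 = destination_point(nest, 90.0, 800.0)
        rays = [
            Beeline(hainich, 0.0, 1200.0, "F1"),
            Beeline(o2, 270.0, 1000.0, "F2"),
        ]
        est = localize_nest(rays)
        assert est.method == "ray-intersection"
        assert distance_between(est.location, nest) < 1.0
        assert est.uncertainty_radius < 1.0

    def test_least_squares_point_matches_grid_search(self, hainich):
        """Noisy 3-ray case against a brute-force planar grid search."""
        frame = LocalFrame(hainich)
        nest = destination_point(hainich, 10.0, 1500.0)
        rays, planar = [], []
        for brg_noise, az in [(4.0, 20.0), (-6.0, 140.0), (3.0, 260.0)]:
            origin = destination_point(nest, az, 1400.0)
            b = (bearing_between(origin, nest) + brg_noise) % 360.0
            rays.append(Beeline(origin, b, 3000.0, f"F{az:.0f}"))
            planar.append((frame.project(origin), b))
        model = NestLocalizationModel(rays)
        res = model.fit()
        gx, gy = grid_search_ray_point(planar)
        oracle_pt = frame.unproject(gx, gy)
        assert distance_between(res.location, oracle_pt) < 2.0
        assert res.uncertainty_radius > 0

    def test_single_ray_with_disc_bound(self, hainich):
        est = localize_nest(
            [Beeline(hainich, 0.0, 10_000.0, "F1"), RangeDisc(hainich, 500.0, "F2")]
        )
        assert est.method == "ray+range"
        target = destination_point(hainich, 0.0, 500.0)
        assert distance_between(est.location, target) < 1.0

    def test_discs_only_centroid(self, hainich):
        c2 = destination_point(hainich, 90.0, 800.0)
        est = localize_nest([RangeDisc(hainich, 600.0, "a"), RangeDisc(c2, 600.0, "b")])
        assert est.method == "range-only"
        midpoint = destination_point(hainich, 90.0, 400.0)
        assert distance_between(est.location, midpoint) < 5.0
        assert est.consistent

    def test_parallel_rays_without_disc_unlocalizable(self, hainich):
        o2 = destination_point(hainich, 90.0, 50.0)
        with pytest.raises(UnlocalizableError):
            localize_nest([Beeline(hainich, 0.0, 1000.0), Beeline(o2, 1.0, 1000.0)])

    def test_disjoint_discs_flagged_inconsistent(self, hainich):
        far = destination_point(hainich, 90.0, 5000.0)
        with pytest.warns(UserWarning, match="empty"):
            est = localize_nest([RangeDisc(hainich, 400.0), RangeDisc(far, 400.0)])
        assert not est.consistent

    def test_estimate_clipped_into_range_bounds(self, hainich):
        # two nearly parallel rays crossing far beyond their max ranges
        o2 = destination_point(hainich, 90.0, 100.0)
        rays = [
            Beeline(hainich, 5.0, 700.0, "F1"),
            Beeline(o2, 0.0, 700.0, "F2"),
        ]
        est = localize_nest(rays)
        assert est.method == "ray+range"
        assert distance_between(est.location, hainich) <= 702.0


class TestMergeEstimates:
    def test_nearby_estimates_merge(self, hainich):
        near = destination_point(hainich, 45.0, 200.0)
        far = destination_point(hainich, 45.0, 3000.0)
        ests = [
            localize_nest([RangeDisc(p, 300.0, f"F{i}")])
            for i, p in enumerate([hainich, near, far])
        ]
        merged = merge_nest_estimates(ests, merge_radius=500.0)
        assert len(merged) == 2

    def test_merged_estimate_pools_feeders(self, hainich):
        near = destination_point(hainich, 0.0, 100.0)
        ests = [
            localize_nest([RangeDisc(hainich, 300.0, "F1")]),
            localize_nest([RangeDisc(near, 300.0, "F2")]),
        ]
        (merged,) = merge_nest_estimates(ests)
        assert set(merged.supporting_feeders) == {"F1", "F2"}


class TestSurveyArea:
    def test_single_site(self, hainich):
        assert survey_area([hainich], 2000.0) == pytest.approx(math.pi * 4.0, rel=1e-3)

    def test_disjoint_sites_add(self, hainich):
        other = destination_point(hainich, 90.0, 5000.0)
        assert survey_area([hainich, other], 2000.0) == pytest.approx(
            2 * math.pi * 4.0, rel=1e-3
        )

    def test_coincident_sites_do_not_double_count(self, hainich):
        assert survey_area([hainich, hainich], 2000.0) == pytest.approx(
            math.pi * 4.0, rel=1e-3
        )

    def test_overlapping_union_matches_monte_carlo(self, hainich):
        sites = [
            hainich,
            destination_point(hainich, 90.0, 2500.0),
            destination_point(hainich, 20.0, 1500.0),
        ]
        area = survey_area(sites, 2000.0)
        frame = LocalFrame.centered_on(sites)
        mc = monte_carlo_union_area_km2([frame.project(s) for s in sites], 2000.0)
        assert area == pytest.approx(mc, rel=0.01)


class TestDensityFromSurvey:
    def test_yearly_survey_densities(self):
        assert density_from_survey(4, 30.58).rounded() == 0.13
        assert density_from_survey(6, 43.23).rounded() == 0.14

    def test_zero_nests(self):
        assert density_from_survey(0, 10.0).value == 0.0

    def test_product_recovers_count(self):
        est = density_from_survey(7, 49.5)
        assert est.value * est.denominator_km2 == pytest.approx(7.0, rel=1e-12)

    def test_bad_area_rejected(self):
        with pytest.raises(ValueError):
            density_from_survey(1, 0.0)
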