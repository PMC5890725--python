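"""Dance decoding: piecewise calibration, bearings, summaries, comparisons."""

import math
from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from beetracker import (
    CalibrationRangeError,
    DanceRecord,
    GeoPoint,
    SwarmDispersalModel,
    circuit_duration_to_distance,
    compare_swarms,
    dance_bearing,
    decode_dance,
    destination_point,
    distance_between,
    distance_to_circuit_duration,
    solar_azimuth,
    summarize_swarm,
)
from beetracker.dance import BREAKPOINT_S
from _oracles import kruskal_wallis_h, kruskal_wallis_permutation_p


class TestDistanceCalibration:
    @pytest.mark.parametrize(
        "duration, expected",
        [(2.00, 258.07), (3.15, 794.60), (4.00, 1744.31)],
    )
    def test_branch_values(self, duration, expected):
        assert circuit_duration_to_distance(duration) == pytest.approx(expected, abs=0.005)

    def test_breakpoint_inclusive_on_near_branch(self):
        at = circuit_duration_to_distance(BREAKPOINT_S)
        just_above = circuit_duration_to_distance(math.nextafter(BREAKPOINT_S, 4))
        assert at < just_above  # far branch sits above the near branch here

    def test_branch_discontinuity_magnitude(self):
        gap = circuit_duration_to_distance(
            math.nextafter(BREAKPOINT_S, 4)
        ) - circuit_duration_to_distance(BREAKPOINT_S)
        assert gap == pytest.approx(12.39, abs=0.01)
        assert gap < 15.0

    def test_below_calibration_root_rejected(self):
        with pytest.raises(CalibrationRangeError):
            circuit_duration_to_distance(1.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=1.5, max_value=8.0))
    def test_monotone_nondecreasing(self, t):
        assert circuit_duration_to_distance(t + 0.01) >= circuit_duration_to_distance(t)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=100.0, max_value=6000.0))
    def test_inverse_round_trip_outside_gap(self, d):
        t = distance_to_circuit_duration(d)
        back = circuit_duration_to_distance(t)
        # distances inside the ~794.6-807.0 m branch gap snap to an endpoint
        assert back == pytest.approx(d, abs=13.0)
        if not 794.0 < d < 808.0:
            assert back == pytest.approx(d, abs=1e-6)


class TestDanceBearing:
    @pytest.mark.parametrize(
        "angle, azimuth, expected",
        [(0.0, 180.0, 180.0), (90.0, 300.0, 30.0), (360.0, 0.0, 0.0)],
    )
    def test_addition_mod_360(self, angle, azimuth, expected):
        assert dance_bearing(angle, azimuth) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-720, 720), st.floats(0, 360, exclude_max=True))
    def test_output_range(self, angle, azimuth):
        assert 0.0 <= dance_bearing(angle, azimuth) < 360.0


class TestDecodeDance:
    def test_round_trip_recovers_site(self, hainich):
        """Encoding a known site into a dance and decoding returns the site."""
        t = datetime(2017, 8, 15, 13, 30, tzinfo=timezone.utc)
        site = destination_point(hainich, 123.0, 1900.0)
        true_bearing = 123.0
        azimuth = solar_azimuth(hainich, t)
        record = DanceRecord(
            swarm_id="S1",
            swarm_location=hainich,
            time_utc=t,
            circuit_duration_s=distance_to_circuit_duration(1900.0),
            dance_angle_deg=(true_bearing - azimuth) % 360.0,
        )
        advert = decode_dance(record)
        assert distance_between(advert.location, site) < 1.0

    def test_below_range_propagates(self, hainich):
        record = DanceRecord(
            "S1", hainich, datetime(2017, 8, 15, 13, 0, tzinfo=timezone.utc), 1.0, 0.0
        )
        with pytest.raises(CalibrationRangeError):
            decode_dance(record)

    def test_signed_angles_normalized(self, hainich):
        r = DanceRecord(
            "S1", hainich, datetime(2017, 8, 15, 13, 0, tzinfo=timezone.utc), 2.5, -90.0
        )
        assert r.dance_angle_deg == 270.0


class TestSummaries:
    def test_single_advert(self):
        s = summarize_swarm([300.0], "S")
        assert s.median == s.p95 == 300.0

    def test_median_of_three(self):
        assert summarize_swarm([100.0, 200.0, 300.0], "S").median == 200.0

    def test_p95_linear_interpolation(self):
        s = summarize_swarm([float(i) for i in range(1, 101)], "S")
        assert s.p95 == pytest.approx(95.05)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_scaling_equivariance(self, k):
        base = [120.0, 300.0, 450.0, 800.0, 2500.0]
        s1 = summarize_swarm(base, "S")
        s2 = summarize_swarm([k * v for v in base], "S")
        assert s2.median == pytest.approx(k * s1.median, rel=1e-12)
        assert s2.p95 == pytest.approx(k * s1.p95, rel=1e-12)


class TestCompareSwarms:
    GROUPS = {
        "a": [120.0, 340.0, 560.0],
        "b": [210.0, 900.0, 1500.0],
        "c": [260.0, 330.0, 1800.0],
    }

    def test_identical_groups_degenerate(self):
        res = compare_swarms({"a": [5.0, 5.0], "b": [5.0, 5.0], "c": [5.0]})
        assert res.h_statistic == 0.0
        assert res.p_value == 1.0

    def test_h_matches_explicit_rank_formula(self):
        res = compare_swarms(self.GROUPS)
        assert res.h_statistic == pytest.approx(
            kruskal_wallis_h(list(self.GROUPS.values())), rel=1e-12
        )

    def test_h_with_ties_matches_oracle(self):
        groups = {"a": [1.0, 2.0, 2.0], "b": [2.0, 3.0, 5.0], "c": [5.0, 5.0, 9.0]}
        res = compare_swarms(groups)
        assert res.h_statistic == pytest.approx(
            kruskal_wallis_h(list(groups.values())), rel=1e-12
        )

    def test_chi_square_p_close_to_exact_permutation(self):
        """The chi-square approximation is coarse at n=(3,3,3): tolerance 0.15."""
        res = compare_swarms(self.GROUPS)
        p_exact = kruskal_wallis_permutation_p(list(self.GROUPS.values()))
        assert abs(res.p_value - p_exact) < 0.15

    def test_h_invariant_under_monotone_transform(self):
        res1 = compare_swarms(self.GROUPS)
        res2 = compare_swarms({k: [math.log(v) for v in g] for k, g in self.GROUPS.items()})
        assert res1.h_statistic == pytest.approx(res2.h_statistic, rel=1e-12)

    def test_dunn_z_matches_hand_computation(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        res = compare_swarms(groups)
        # pooled ranks 1..6, no ties: mean ranks 2 and 5,
        # z = (2-5)/sqrt((6*7/12)*(1/3+1/3)) = -3/sqrt(7/3)
        expected = -3.0 / math.sqrt(7.0 / 3.0)
        row = res.dunn.iloc[0]
        assert row.z == pytest.approx(expected, rel=1e-12)
        assert row.p_unadjusted == pytest.approx(2 * stats.norm.sf(abs(expected)), rel=1e-12)

    def test_holm_adjustment_monotone(self):
        res = compare_swarms(self.GROUPS)
        assert (res.dunn["p_holm"] >= res.dunn["p_unadjusted"] - 1e-15).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_swarms({"a": [1.0]})
        with pytest.raises(ValueError):
            compare_swarms({"a": [1.0], "b": []})


class TestSwarmDispersalModel:
    def test_fit_reports_per_swarm_and_cross_swarm(self, hainich):
        t0 = datetime(2017, 8, 15, 12, 0, tzinfo=timezone.utc)
        records = []
        for swarm, base in [("near", 400.0), ("far", 2500.0)]:
            for i, extra in enumerate([0.0, 150.0, 900.0]):
                azimuth = solar_azimuth(hainich, t0)
                records.append(
                    DanceRecord(
                        swarm_id=swarm,
                        swarm_location=hainich,
                        time_utc=t0,
                        circuit_duration_s=distance_to_circuit_duration(base + extra),
                        dance_angle_deg=(40.0 * i - azimuth) % 360.0,
                    )
                )
        results = SwarmDispersalModel(records).fit()
        assert {s.swarm_id for s in results.summaries} == {"near", "far"}
        near = next(s for s in results.summaries if s.swarm_id == "near")
        assert near.median == pytest.approx(550.0, abs=15.0)  # snap in branch gap
        assert results.comparison is not None
        assert "Kruskal-Wallis" in results.summary()
        assert results.average_median == pytest.approx(
            np.mean([s.median for s in results.summaries])
        )
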