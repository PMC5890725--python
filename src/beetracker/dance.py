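"""Waggle-dance decoding of scout-advertised nest sites on swarms.

A scout bee returning from a candidate cavity dances on the swarm cluster.
Two quantities are read off each dance: the mean duration of a full dance
circuit (waggle run + return loop), which encodes distance through a
piecewise-linear calibration derived from von Frisch's original
distance/circuit-duration data, and the waggle-run angle relative to
vertical, which encodes the flight direction relative to the sun.  Adding
the solar azimuth at dance time to the dance angle therefore yields the true
compass bearing, and projecting that distance and bearing from the swarm
location gives the advertised site's coordinates.

The calibration::

    distance (m) = 466.5495 * circuit_duration (s) -  675.0336   (<= 3.15 s)
    distance (m) = 1102.7328 * circuit_duration (s) - 2666.6256   (> 3.15 s)

is only valid above the positive root of the first branch (~1.447 s,
~100 m); shorter circuits are below calibration range.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from datetime import datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geodesy import GeoPoint, destination_point, normalize_bearing, solar_azimuth

__all__ = [
    "BREAKPOINT_S",
    "CalibrationRangeError",
    "circuit_duration_to_distance",
    "distance_to_circuit_duration",
    "dance_bearing",
    "DanceRecord",
    "NestSiteAdvert",
    "decode_dance",
    "DistanceSummary",
    "summarize_swarm",
    "SwarmComparison",
    "compare_swarms",
    "SwarmDispersalModel",
    "SwarmDispersalResults",
]

BREAKPOINT_S = 3.15
SLOPE_NEAR = 466.5495
INTERCEPT_NEAR = 675.0336
SLOPE_FAR = 1102.7328
INTERCEPT_FAR = 2666.6256

#: positive root of the near branch: durations at/below decode to <= 0 m
CALIBRATION_ROOT_S = INTERCEPT_NEAR / SLOPE_NEAR

#: shortest distance the original calibration data cover
MIN_CALIBRATED_DISTANCE_M = 100.0

#: distance at the top of the near branch (duration exactly 3.15 s)
_NEAR_MAX_M = SLOPE_NEAR * BREAKPOINT_S - INTERCEPT_NEAR
#: distance at the bottom of the far branch (duration just above 3.15 s)
_FAR_MIN_M = SLOPE_FAR * BREAKPOINT_S - INTERCEPT_FAR


class CalibrationRangeError(ValueError):
    """Circuit duration below the calibration range of the regression."""


def circuit_duration_to_distance(duration_s: float) -> float:
    """Nest-site distance (m) encoded by a dance-circuit duration (s).

    Durations up to and including 3.15 s use the near-range branch, longer
    ones the far-range branch; each branch is strictly increasing.
    """
    if duration_s <= CALIBRATION_ROOT_S:
        raise CalibrationRangeError(
            f"circuit duration {duration_s:.3f} s is at/below the calibration "
            f"root ({CALIBRATION_ROOT_S:.4f} s, ~100 m)"
        )
    if duration_s <= BREAKPOINT_S:
        return SLOPE_NEAR * duration_s - INTERCEPT_NEAR
    return SLOPE_FAR * duration_s - INTERCEPT_FAR


def distance_to_circuit_duration(distance_m: float) -> float:
    """Inverse calibration: the circuit duration advertising a distance.

    Distances inside the small discontinuity gap between the branches
    (~794.6-807.0 m) have no exact preimage; they are snapped to the nearer
    branch endpoint.  Distances below 100 m are outside the range the
    original calibration data cover and cannot be encoded.
    """
    if distance_m < MIN_CALIBRATED_DISTANCE_M:
        raise CalibrationRangeError(
            f"distance {distance_m:.1f} m below calibrated range "
            f"(>= {MIN_CALIBRATED_DISTANCE_M:.0f} m)"
        )
    if distance_m <= _NEAR_MAX_M:
        return (distance_m + INTERCEPT_NEAR) / SLOPE_NEAR
    if distance_m >= _FAR_MIN_M:
        return (distance_m + INTERCEPT_FAR) / SLOPE_FAR
    # gap between branches: snap to whichever endpoint is closer
    if distance_m - _NEAR_MAX_M <= _FAR_MIN_M - distance_m:
        return BREAKPOINT_S
    return math.nextafter(BREAKPOINT_S, math.inf)


def dance_bearing(dance_angle_deg: float, azimuth_deg: float) -> float:
    """True compass bearing: dance angle from vertical plus solar azimuth."""
    if not (math.isfinite(dance_angle_deg) and math.isfinite(azimuth_deg)):
        raise ValueError("angle and azimuth must be finite")
    return normalize_bearing(dance_angle_deg + azimuth_deg)


@dataclass(frozen=True)
class DanceRecord:
    """One observed scout dance on a swarm cluster."""

    swarm_id: str
    swarm_location: GeoPoint
    time_utc: datetime
    circuit_duration_s: float  # mean over ~6 consecutive circuits
    dance_angle_deg: float  # clockwise from vertical; signed input accepted
    n_circuits: int | None = None

    def __post_init__(self) -> None:
        if self.circuit_duration_s <= 0:
            raise ValueError("circuit duration must be positive")
        object.__setattr__(self, "dance_angle_deg", normalize_bearing(self.dance_angle_deg))


@dataclass(frozen=True)
class NestSiteAdvert:
    """A decoded dance: where the scout says the candidate cavity is."""

    swarm_id: str
    distance: float
    bearing: float
    location: GeoPoint


def decode_dance(record: DanceRecord) -> NestSiteAdvert:
    """Decode one dance into an advertised nest-site location."""
    dist = circuit_duration_to_distance(record.circuit_duration_s)
    azi = solar_azimuth(record.swarm_location, record.time_utc)
    brg = dance_bearing(record.dance_angle_deg, azi)
    loc = destination_point(record.swarm_location, brg, dist)
    return NestSiteAdvert(record.swarm_id, dist, brg, loc)


@dataclass(frozen=True)
class DistanceSummary:
    """Per-swarm advertised-distance summary (median and 95th percentile)."""

    swarm_id: str
    n: int
    median: float
    p95: float


def _distances(adverts: Sequence[NestSiteAdvert | float]) -> np.ndarray:
    vals = np.asarray(
        [a.distance if isinstance(a, NestSiteAdvert) else float(a) for a in adverts]
    )
    if vals.size == 0:
        raise ValueError("no adverts given")
    return vals


def summarize_swarm(
    adverts: Sequence[NestSiteAdvert | float], swarm_id: str = ""
) -> DistanceSummary:
    """Median and 95th percentile of advertised distances for one swarm.

    Percentiles use linear interpolation between closest ranks; other rules
    shift the upper percentile by a few tens of meters on samples this size.
    """
    d = _distances(adverts)
    if isinstance(adverts[0], NestSiteAdvert) and not swarm_id:
        swarm_id = adverts[0].swarm_id
    return DistanceSummary(
        swarm_id=swarm_id,
        n=d.size,
        median=float(np.percentile(d, 50)),
        p95=float(np.percentile(d, 95)),
    )


@dataclass(frozen=True)
class SwarmComparison:
    """Kruskal-Wallis test across swarms plus pairwise Dunn z-tests.

    ``dunn`` holds one row per swarm pair with the rank-based z statistic,
    the unadjusted two-sided normal p-value, and its Holm adjustment.
    """

    h_statistic: float
    df: int
    p_value: float
    dunn: pd.DataFrame


def compare_swarms(groups: Mapping[str, Sequence[float]]) -> SwarmComparison:
    """Compare advertised-distance distributions across swarms.

    Kruskal-Wallis H (with tie correction, chi-square p on k-1 df) tests
    overall homogeneity; Dunn's z-tests on the pooled ranks localize which
    swarm pairs differ.  When every value is identical the test is degenerate
    and reported as H = 0, p = 1.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(s.size == 0 for s in samples):
        raise ValueError("every group needs at least one value")

    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)

    # Dunn's pairwise z on pooled mid-ranks with tie correction
    ranks = stats.rankdata(pooled)
    n_tot = pooled.size
    splits = np.cumsum([s.size for s in samples])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = {k: float(r.mean()) for k, r in zip(labels, group_ranks)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    rows = []
    for (la, sa), (lb, sb) in itertools.combinations(zip(labels, samples), 2):
        se = math.sqrt(var_base * (1.0 / sa.size + 1.0 / sb.size))
        z = (mean_ranks[la] - mean_ranks[lb]) / se if se > 0 else 0.0
        p_un = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": la, "group_b": lb, "z": z, "p_unadjusted": p_un})
    dunn = pd.DataFrame(rows)
    if len(dunn):
        dunn["p_holm"] = multipletests(dunn["p_unadjusted"], method="holm")[1]
    return SwarmComparison(float(h), len(labels) - 1, float(p), dunn)


class SwarmDispersalModel:
    """Dance-decoding analysis of one or more observed swarms.

    Decodes every dance record into an advertised nest site, summarizes the
    per-swarm distance distributions, and — with at least two swarms —
    tests whether the swarms advertised sites at different distances.
    """

    def __init__(self, records: Sequence[DanceRecord]):
        if not records:
            raise ValueError("need at least one dance record")
        self.records = list(records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SwarmDispersalModel":
        """Build from a table with the advertised-nest-sites schema.

        Required columns: ``swarm_id, lat, lon, time_utc, circuit_duration_s,
        dance_angle_deg``; optional ``n_circuits``.
        """
        from .io import dance_records_from_frame

        return cls(dance_records_from_frame(df))

    def fit(self) -> "SwarmDispersalResults":
        adverts = [decode_dance(r) for r in self.records]
        by_swarm: dict[str, list[NestSiteAdvert]] = {}
        for a in adverts:
            by_swarm.setdefault(a.swarm_id, []).append(a)
        summaries = [summarize_swarm(v, k) for k, v in by_swarm.items()]
        comparison = None
        if len(by_swarm) >= 2:
            comparison = compare_swarms(
                {k: [a.distance for a in v] for k, v in by_swarm.items()}
            )
        return SwarmDispersalResults(self, adverts, summaries, comparison)


class SwarmDispersalResults:
    """Decoded adverts, per-swarm summaries and the cross-swarm test."""

    def __init__(self, model, adverts, summaries, comparison):
        self.model = model
        self.adverts: list[NestSiteAdvert] = adverts
        self.summaries: list[DistanceSummary] = summaries
        self.comparison: SwarmComparison | None = comparison

    @property
    def average_median(self) -> float:
        """Arithmetic mean of the per-swarm medians, in meters."""
        return float(np.mean([s.median for s in self.summaries]))

    @property
    def average_p95(self) -> float:
        """Arithmetic mean of the per-swarm 95th percentiles, in meters."""
        return float(np.mean([s.p95 for s in self.summaries]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "swarm_id": [a.swarm_id for a in self.adverts],
                "distance_m": [a.distance for a in self.adverts],
                "bearing_deg": [a.bearing for a in self.adverts],
                "lat": [a.location.lat for a in self.adverts],
                "lon": [a.location.lon for a in self.adverts],
            }
        )

    def summary(self) -> str:
        lines = [
            "Swarm dispersal (decoded nest-site dances)",
            "=" * 48,
            f"{'swarm':<14}{'n':>5}{'median (m)':>14}{'p95 (m)':>12}",
        ]
        for s in self.summaries:
            lines.append(f"{s.swarm_id:<14}{s.n:>5}{s.median:>14.0f}{s.p95:>12.0f}")
        lines.append(
            f"{'average':<14}{sum(s.n for s in self.summaries):>5}"
            f"{self.average_median:>14.0f}{self.average_p95:>12.0f}"
        )
        if self.comparison is not None:
            c = self.comparison
            lines += [
                "",
                f"Kruskal-Wallis: H = {c.h_statistic:.2f}, df = {c.df}, "
                f"P = {c.p_value:.4f}",
                "Dunn pairwise (z, unadjusted P, Holm P):",
            ]
            for _, r in c.dunn.iterrows():
                lines.append(
                    f"  {r.group_a} vs {r.group_b}: z = {r.z:+.2f}, "
                    f"P = {r.p_unadjusted:.4f}, Holm = {r.p_holm:.4f}"
                )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Histogram of advertised distances per swarm with median/p95 marks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        for swarm, sub in df.groupby("swarm_id"):
            ax.hist(sub["distance_m"], bins=20, alpha=0.5, label=str(swarm))
        for s in self.summaries:
            ax.axvline(s.median, ls="-", lw=1)
            ax.axvline(s.p95, ls="--", lw=1)
        ax.set_xlabel("advertised nest-site distance (m)")
        ax.set_ylabel("dances")
        ax.legend()
        return ax
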