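"""Beelining: nest localization from forager round-trip times and bearings.

A marked forager's round-trip time at a feeder bounds the distance to its
nest through the empirical calibration ``distance (m) = 243 * t (min) -
627.75`` applied to the fastest bee (slower bees linger inside the nest, so
only the fastest trip is informative).  The mean vanishing bearing gives the
flight direction.  Each feeder therefore contributes either a directed ray
with a maximum range (a *beeline*) or, when no bearing could be read under
the canopy, a range-only disc.  Nest localization combines these constraints:
crossing rays are intersected in the least-squares sense, single rays are
truncated by range bounds, and bare discs are intersected directly.

Colony density follows by counting distinct nests inside the union of 2-km
buffers around the sampling sites — 2 km being the radius honey bee foraging
(and hence feeder recruitment) normally covers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from shapely.geometry import Point
from shapely.ops import nearest_points, unary_union

from .density import DensityEstimate
from .geodesy import GeoPoint, LocalFrame, bearing_between, distance_between, normalize_bearing

__all__ = [
    "ROUND_TRIP_SLOPE_M_PER_MIN",
    "ROUND_TRIP_INTERCEPT_M",
    "FeederStation",
    "BeelineObservation",
    "Beeline",
    "RangeDisc",
    "NestEstimate",
    "UnlocalizableError",
    "max_nest_distance",
    "round_trip_for_distance",
    "fastest_bee",
    "circular_mean",
    "make_beeline",
    "localize_nest",
    "NestLocalizationModel",
    "NestLocalizationResults",
    "merge_nest_estimates",
    "survey_area",
    "density_from_survey",
]

ROUND_TRIP_SLOPE_M_PER_MIN = 243.0
ROUND_TRIP_INTERCEPT_M = 627.75

#: below this round-trip time the affine calibration would go negative
MIN_INFORMATIVE_TRIP_MIN = ROUND_TRIP_INTERCEPT_M / ROUND_TRIP_SLOPE_M_PER_MIN

#: rays whose bearings all agree within this tolerance (mod 180) cannot be
#: intersected meaningfully
PARALLEL_TOLERANCE_DEG = 2.0

_BUFFER_SEGMENTS = 64  # quarter-circle segments -> 256-gon discs


@dataclass(frozen=True)
class FeederStation:
    """An artificial feeding site where foragers were caught and marked."""

    id: str
    location: GeoPoint
    site: str | None = None
    session: str | None = None
    hunt: str | None = None  # label grouping feeders that chased one nest


@dataclass(frozen=True)
class BeelineObservation:
    """One marked forager's record at a feeder.

    Either field may be missing in raw data; rows lacking a round-trip time
    carry no range information and rows lacking a bearing no direction.
    """

    feeder_id: str
    bee_id: str | None = None
    round_trip_min: float | None = None
    vanishing_bearing: float | None = None

    def __post_init__(self) -> None:
        if self.round_trip_min is not None and self.round_trip_min <= 0:
            raise ValueError("round-trip time must be positive")
        if self.vanishing_bearing is not None:
            object.__setattr__(
                self, "vanishing_bearing", normalize_bearing(self.vanishing_bearing)
            )


@dataclass(frozen=True)
class Beeline:
    """A directed nest constraint: ray from a feeder with a maximum range."""

    origin: GeoPoint
    bearing: float
    max_distance: float
    feeder_id: str = ""

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        object.__setattr__(self, "bearing", normalize_bearing(self.bearing))


@dataclass(frozen=True)
class RangeDisc:
    """A direction-free nest constraint: the nest lies within ``radius``."""

    center: GeoPoint
    radius: float
    feeder_id: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class NestEstimate:
    """An inferred nest location with uncertainty and supporting evidence."""

    location: GeoPoint
    uncertainty_radius: float
    supporting_feeders: tuple[str, ...]
    method: str  # "ray-intersection" | "ray+range" | "range-only"
    consistent: bool = True

    def __post_init__(self) -> None:
        if self.uncertainty_radius < 0:
            raise ValueError("uncertainty radius cannot be negative")
        if not self.supporting_feeders:
            raise ValueError("an estimate needs at least one supporting feeder")


class UnlocalizableError(ValueError):
    """Raised when the constraints cannot pin down a nest location."""


def max_nest_distance(round_trip_min: float) -> float:
    """Maximum feeder-to-nest distance implied by a round-trip time.

    Applies ``243 * t - 627.75``; times at or below the positive root
    (~2.58 min) mean the nest is essentially adjacent to the feeder and are
    reported as 0 m with a warning rather than a negative distance.
    """
    if round_trip_min <= 0:
        raise ValueError("round-trip time must be positive")
    d = ROUND_TRIP_SLOPE_M_PER_MIN * round_trip_min - ROUND_TRIP_INTERCEPT_M
    if d <= 0:
        warnings.warn(
            f"round trip of {round_trip_min:.2f} min is at/below the calibration "
            "root; nest adjacent to feeder (distance reported as 0)",
            stacklevel=2,
        )
        return 0.0
    return d


def round_trip_for_distance(distance_m: float) -> float:
    """Inverse calibration: the deterministic round-trip time for a distance."""
    if distance_m < 0:
        raise ValueError("distance must be non-negative")
    return (distance_m + ROUND_TRIP_INTERCEPT_M) / ROUND_TRIP_SLOPE_M_PER_MIN


def fastest_bee(observations: Sequence[BeelineObservation]) -> BeelineObservation:
    """The observation with the minimum round-trip time (ties: first listed)."""
    timed = [o for o in observations if o.round_trip_min is not None]
    if not timed:
        raise ValueError("no observation carries a round-trip time")
    return min(timed, key=lambda o: o.round_trip_min)


def circular_mean(bearings_deg: Sequence[float]) -> float:
    """Vector mean of compass bearings, wrap-aware, in ``[0, 360)``."""
    if len(bearings_deg) == 0:
        raise ValueError("no bearings given")
    rad = np.radians(np.asarray(bearings_deg, dtype=float))
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    if math.hypot(s, c) < 1e-12:
        raise ValueError("bearings cancel out; mean direction undefined")
    return normalize_bearing(math.degrees(math.atan2(s, c)))


def make_beeline(
    feeder: FeederStation, observations: Sequence[BeelineObservation]
) -> Beeline | RangeDisc:
    """Aggregate one feeder's observations into a single constraint.

    The range comes from the fastest bee; the direction is the circular mean
    of all available vanishing bearings.  Without any bearing the feeder
    yields a range-only disc.
    """
    fastest = fastest_bee(observations)
    dist = max_nest_distance(fastest.round_trip_min)
    if dist <= 0:
        dist = 1.0  # adjacent nest: keep a tiny but valid constraint
    bearings = [o.vanishing_bearing for o in observations if o.vanishing_bearing is not None]
    if bearings:
        return Beeline(feeder.location, circular_mean(bearings), dist, feeder.id)
    return RangeDisc(feeder.location, dist, feeder.id)


# --- localization -----------------------------------------------------------


class NestLocalizationModel:
    """Least-squares nest localization from beelines and range discs.

    With two or more non-parallel rays the estimate minimizes the summed
    squared perpendicular distances to the rays (solved in a local planar
    frame), clipped into the intersection of all range bounds if it falls
    outside.  A single ray is truncated at the tightest range bound along it;
    discs alone are intersected and their region's centroid taken.  Range
    bounds are treated as soft (clip, not reject): round-trip times
    overestimate distance whenever a bee lingered in the nest, so an estimate
    slightly beyond a bound is attributed to that bias, flagged, and pulled
    back rather than discarded.
    """

    def __init__(self, constraints: Sequence[Beeline | RangeDisc]):
        if not constraints:
            raise ValueError("need at least one constraint")
        self.rays: list[Beeline] = [c for c in constraints if isinstance(c, Beeline)]
        self.discs: list[RangeDisc] = [c for c in constraints if isinstance(c, RangeDisc)]
        origins = [c.origin if isinstance(c, Beeline) else c.center for c in constraints]
        self.frame = LocalFrame.centered_on(origins)

    @classmethod
    def from_observations(
        cls,
        feeders: Sequence[FeederStation],
        observations: Sequence[BeelineObservation],
    ) -> "NestLocalizationModel":
        """Build constraints per feeder from raw observation rows."""
        by_feeder: dict[str, list[BeelineObservation]] = {}
        for o in observations:
            by_feeder.setdefault(o.feeder_id, []).append(o)
        constraints = [
            make_beeline(f, by_feeder[f.id]) for f in feeders if by_feeder.get(f.id)
        ]
        return cls(constraints)

    # planar helpers ---------------------------------------------------

    def _ray_geom(self, ray: Beeline) -> tuple[np.ndarray, np.ndarray]:
        p = np.array(self.frame.project(ray.origin))
        theta = math.radians(ray.bearing)
        u = np.array([math.sin(theta), math.cos(theta)])  # x east, y north
        return p, u

    def _range_region(self):
        """Shapely intersection of every range bound (ray ranges + discs).

        Radii get ~1 m of slack: the bounds are soft (round-trip times only
        overestimate distance) and the 256-gon discs inscribe the true
        circles, so a nest exactly at maximum range must still count as
        inside.
        """

        def slack(r: float) -> float:
            return r + 1.0 + 1e-4 * r

        shapes = []
        for ray in self.rays:
            p, _ = self._ray_geom(ray)
            shapes.append(Point(p).buffer(slack(ray.max_distance), quad_segs=_BUFFER_SEGMENTS))
        for disc in self.discs:
            c = np.array(self.frame.project(disc.center))
            shapes.append(Point(c).buffer(slack(disc.radius), quad_segs=_BUFFER_SEGMENTS))
        region = shapes[0]
        for s in shapes[1:]:
            region = region.intersection(s)
        return region

    def _rays_parallel(self) -> bool:
        axes = [r.bearing % 180.0 for r in self.rays]
        for i in range(len(axes)):
            for j in range(i + 1, len(axes)):
                d = abs(axes[i] - axes[j])
                if min(d, 180.0 - d) > PARALLEL_TOLERANCE_DEG:
                    return False
        return True

    def fit(self) -> "NestLocalizationResults":
        if len(self.rays) >= 2 and not self._rays_parallel():
            return self._fit_ray_intersection()
        if len(self.rays) >= 2 and not self.discs:
            raise UnlocalizableError(
                "all rays parallel within "
                f"{PARALLEL_TOLERANCE_DEG} degrees and no range disc available"
            )
        if len(self.rays) >= 1:
            return self._fit_single_ray()
        return self._fit_discs_only()

    def _fit_ray_intersection(self) -> "NestLocalizationResults":
        # minimize sum_i (n_i . (x - p_i))^2 with n_i the unit normal of ray i
        A = np.zeros((2, 2))
        b = np.zeros(2)
        geoms = [self._ray_geom(r) for r in self.rays]
        for p, u in geoms:
            n = np.array([-u[1], u[0]])
            A += np.outer(n, n)
            b += np.outer(n, n) @ p
        x = np.linalg.solve(A, b)
        method = "ray-intersection"
        consistent = True
        region = self._range_region()
        if region.is_empty:
            consistent = False
        elif not region.intersects(Point(x)):
            nearest = nearest_points(region, Point(x))[0]
            x = np.array([nearest.x, nearest.y])
            method = "ray+range"
        residuals = np.array([abs(np.dot([-u[1], u[0]], x - p)) for p, u in geoms])
        rms = float(np.sqrt(np.mean(residuals**2)))
        return self._results(x, rms, method, consistent, residuals)

    def _fit_single_ray(self) -> "NestLocalizationResults":
        ray = self.rays[0]
        p, u = self._ray_geom(ray)
        bounds: list[float] = [ray.max_distance]
        entries: list[float] = [0.0]
        consistent = True
        for disc in self.discs:
            c = np.array(self.frame.project(disc.center))
            # solve |p + t u - c| = r for t along the ray
            w = p - c
            bq = 2.0 * float(np.dot(u, w))
            cq = float(np.dot(w, w)) - disc.radius**2
            disc_disc = bq * bq - 4.0 * cq
            if disc_disc < 0:
                consistent = False  # ray misses this disc entirely
                continue
            t_lo = (-bq - math.sqrt(disc_disc)) / 2.0
            t_hi = (-bq + math.sqrt(disc_disc)) / 2.0
            if t_hi <= 0:
                consistent = False  # disc lies behind the feeder
                continue
            bounds.append(t_hi)
            entries.append(max(0.0, t_lo))
        d = min(bounds)
        entry = max(entries)
        if entry > d:
            consistent = False
            entry = d
        x = p + d * u
        uncertainty = (d - entry) / 2.0
        return self._results(x, uncertainty, "ray+range", consistent, np.array([]))

    def _fit_discs_only(self) -> "NestLocalizationResults":
        region = self._range_region()
        if region.is_empty:
            warnings.warn(
                "range discs have empty intersection; returning least-squares "
                "compromise point",
                stacklevel=2,
            )
            centers = [np.array(self.frame.project(d.center)) for d in self.discs]
            radii = [d.radius for d in self.discs]

            def violation(x):
                return sum(
                    max(0.0, float(np.linalg.norm(x - c)) - r) ** 2
                    for c, r in zip(centers, radii)
                )

            x0 = np.mean(centers, axis=0)
            res = minimize(violation, x0, method="Nelder-Mead")
            x = res.x
            rms = math.sqrt(violation(x) / len(centers))
            return self._results(x, rms, "range-only", False, np.array([]))
        cen = region.centroid
        x = np.array([cen.x, cen.y])
        boundary = np.asarray(region.exterior.coords)
        uncertainty = float(np.max(np.linalg.norm(boundary - x, axis=1)))
        return self._results(x, uncertainty, "range-only", True, np.array([]))

    def _results(self, xy, uncertainty, method, consistent, residuals):
        feeders = tuple(
            c.feeder_id for c in (*self.rays, *self.discs) if c.feeder_id
        ) or ("<unnamed>",)
        estimate = NestEstimate(
            location=self.frame.unproject(float(xy[0]), float(xy[1])),
            uncertainty_radius=float(uncertainty),
            supporting_feeders=feeders,
            method=method,
            consistent=consistent,
        )
        return NestLocalizationResults(self, estimate, residuals)


class NestLocalizationResults:
    """Fitted nest location with residual diagnostics."""

    def __init__(
        self,
        model: NestLocalizationModel,
        estimate: NestEstimate,
        residuals: np.ndarray,
    ):
        self.model = model
        self.estimate = estimate
        self.residuals = residuals

    @property
    def location(self) -> GeoPoint:
        return self.estimate.location

    @property
    def uncertainty_radius(self) -> float:
        return self.estimate.uncertainty_radius

    @property
    def method(self) -> str:
        return self.estimate.method

    def distance_to(self, point: GeoPoint) -> float:
        """Great-circle error of the estimate relative to a known point."""
        return distance_between(self.location, point)

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Nest localization",
            "=" * 48,
            f"method:              {e.method}",
            f"location:            ({e.location.lat:.6f}, {e.location.lon:.6f})",
            f"uncertainty radius:  {e.uncertainty_radius:.1f} m",
            f"constraints:         {len(self.model.rays)} ray(s), "
            f"{len(self.model.discs)} disc(s)",
            f"supporting feeders:  {', '.join(e.supporting_feeders)}",
            f"consistent:          {e.consistent}",
        ]
        if self.residuals.size:
            lines.append(
                f"perpendicular residuals (m): "
                f"{', '.join(f'{r:.1f}' for r in self.residuals)}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Sketch constraints and the estimate in the local planar frame."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for ray in self.model.rays:
            p, u = self.model._ray_geom(ray)
            end = p + ray.max_distance * u
            ax.plot([p[0], end[0]], [p[1], end[1]], "-", color="tab:blue")
            ax.plot(*p, "^", color="tab:blue")
        for disc in self.model.discs:
            c = self.model.frame.project(disc.center)
            ax.add_patch(
                plt.Circle(c, disc.radius, fill=False, color="tab:orange", ls="--")
            )
        x = self.model.frame.project(self.location)
        ax.plot(*x, "r*", markersize=12)
        ax.add_patch(
            plt.Circle(x, self.uncertainty_radius, fill=False, color="red", alpha=0.5)
        )
        ax.set_aspect("equal")
        ax.set_xlabel("east (m)")
        ax.set_ylabel("north (m)")
        return ax


def localize_nest(constraints: Sequence[Beeline | RangeDisc]) -> NestEstimate:
    """Functional wrapper around :class:`NestLocalizationModel`."""
    return NestLocalizationModel(constraints).fit().estimate


def merge_nest_estimates(
    estimates: Sequence[NestEstimate], merge_radius: float = 500.0
) -> list[NestEstimate]:
    """Merge estimates closer than ``merge_radius`` into single nests.

    Re-detections of one colony across feeders or field seasons land within a
    few hundred meters of each other; single-linkage clustering at the merge
    radius collapses them, averaging locations and pooling evidence.
    """
    if not estimates:
        return []
    n = len(estimates)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if distance_between(estimates[i].location, estimates[j].location) <= merge_radius:
                parent[find(i)] = find(j)

    groups: dict[int, list[NestEstimate]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(estimates[i])

    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        lat = sum(m.location.lat for m in members) / len(members)
        lon = sum(m.location.lon for m in members) / len(members)
        feeders = tuple(dict.fromkeys(f for m in members for f in m.supporting_feeders))
        merged.append(
            NestEstimate(
                location=GeoPoint(lat, lon),
                uncertainty_radius=max(m.uncertainty_radius for m in members),
                supporting_feeders=feeders,
                method=members[0].method,
                consistent=all(m.consistent for m in members),
            )
        )
    merged.sort(key=lambda e: (e.location.lat, e.location.lon))
    return merged


def survey_area(sites: Sequence[GeoPoint], buffer_radius: float = 2000.0) -> float:
    """Area (km²) of the union of discs of ``buffer_radius`` around sites.

    Each sampling site is assumed to attract foragers from the typical
    foraging range (default 2 km), so the union of those discs is the area
    effectively screened for nests.  Discs are 256-gon approximations in a
    local planar frame.
    """
    if not sites:
        raise ValueError("need at least one site")
    if buffer_radius <= 0:
        raise ValueError("buffer radius must be positive")
    frame = LocalFrame.centered_on(list(sites))
    discs = [
        Point(frame.project(s)).buffer(buffer_radius, quad_segs=_BUFFER_SEGMENTS)
        for s in sites
    ]
    return unary_union(discs).area / 1e6


def density_from_survey(n_nests: int, area_km2: float) -> DensityEstimate:
    """Colonies per km² from a nest count over a surveyed area."""
    if n_nests < 0:
        raise ValueError("nest count cannot be negative")
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    return DensityEstimate(
        value=n_nests / area_km2,
        numerator=n_nests,
        denominator_km2=area_km2,
        method="survey-buffer",
        lower_bound=True,
    )
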