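"""Geographic primitives shared by all inference modules.

All geometry is spherical with a mean Earth radius of 6,371,000 m; at the
study scale (nest–feeder and dance ranges below 10 km) the difference from an
ellipsoidal treatment is well under 0.5% and irrelevant next to field
measurement error.  Bearings are degrees clockwise from true north in
``[0, 360)`` throughout, and all timestamps are UTC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone

__all__ = [
    "EARTH_RADIUS_M",
    "GeoPoint",
    "LocalFrame",
    "normalize_bearing",
    "distance_between",
    "bearing_between",
    "destination_point",
    "solar_azimuth",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 latitude/longitude pair in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat!r} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon!r} outside [-180, 180]")


def normalize_bearing(degrees: float) -> float:
    """Reduce an angle in degrees to the compass range ``[0, 360)``."""
    b = math.fmod(degrees, 360.0)
    if b < 0:
        b += 360.0
    return 0.0 if b >= 360.0 else b  # guard: -1e-52 + 360 rounds to 360.0


def distance_between(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle (haversine) distance between two points, in meters."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon - a.lon)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def bearing_between(a: GeoPoint, b: GeoPoint) -> float:
    """Initial great-circle bearing from ``a`` to ``b``, degrees from north.

    Raises ``ValueError`` for coincident points, where the bearing is
    undefined.
    """
    if a.lat == b.lat and a.lon == b.lon:
        raise ValueError("bearing undefined for coincident points")
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dlam = math.radians(b.lon - a.lon)
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    return normalize_bearing(math.degrees(math.atan2(y, x)))


def destination_point(origin: GeoPoint, bearing: float, distance: float) -> GeoPoint:
    """Point reached by travelling ``distance`` meters along ``bearing``.

    Inverse-consistent with :func:`distance_between` and
    :func:`bearing_between` to well under 0.1 m / 0.01 degrees at ranges
    below 10 km.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance == 0:
        return origin
    delta = distance / EARTH_RADIUS_M
    theta = math.radians(normalize_bearing(bearing))
    phi1 = math.radians(origin.lat)
    lam1 = math.radians(origin.lon)
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    )
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    lon = math.degrees(lam2)
    lon = (lon + 180.0) % 360.0 - 180.0
    return GeoPoint(math.degrees(phi2), lon)


class LocalFrame:
    """Equirectangular projection centered on a reference origin.

    Maps geographic coordinates to a local planar (x east, y north) frame in
    meters, for ray intersection and polygon area work.  Within 10 km of the
    origin a project/unproject round trip moves a point by far less than
    0.1 m.
    """

    def __init__(self, origin: GeoPoint):
        self.origin = origin
        self._coslat = math.cos(math.radians(origin.lat))
        self._deg = math.pi / 180.0 * EARTH_RADIUS_M

    @classmethod
    def centered_on(cls, points: list[GeoPoint]) -> "LocalFrame":
        """Frame centered on the centroid of ``points``."""
        if not points:
            raise ValueError("need at least one point")
        lat = sum(p.lat for p in points) / len(points)
        lon = sum(p.lon for p in points) / len(points)
        return cls(GeoPoint(lat, lon))

    def project(self, p: GeoPoint) -> tuple[float, float]:
        x = (p.lon - self.origin.lon) * self._deg * self._coslat
        y = (p.lat - self.origin.lat) * self._deg
        return x, y

    def unproject(self, x: float, y: float) -> GeoPoint:
        lon = self.origin.lon + x / (self._deg * self._coslat)
        lat = self.origin.lat + y / self._deg
        return GeoPoint(lat, lon)


# --- solar position ---------------------------------------------------------
#
# NOAA's solar-position equations (after Meeus, "Astronomical Algorithms").
# Accuracy is a few hundredths of a degree over 1950-2100, ample for decoding
# dance bearings where the field protractor itself reads to ~1 degree.


def _julian_day(t: datetime) -> float:
    if t.tzinfo is None:
        t = t.replace(tzinfo=timezone.utc)
    return 2440587.5 + t.timestamp() / 86400.0


def solar_azimuth(location: GeoPoint, time_utc: datetime) -> float:
    """Sun's compass direction, degrees clockwise from true north.

    ``time_utc`` must be UTC (naive datetimes are taken as UTC) within the
    years 1950-2100.  The azimuth is defined day and night and lies in
    ``[0, 360)``.
    """
    if time_utc.year < 1950 or time_utc.year > 2100:
        raise ValueError(f"time outside supported range 1950-2100: {time_utc}")
    jd = _julian_day(time_utc)
    T = (jd - 2451545.0) / 36525.0

    L0 = (280.46646 + T * (36000.76983 + T * 0.0003032)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = math.radians(M)
    C = (
        math.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + math.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + math.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = math.radians(125.04 - 1934.136 * T)
    app_long = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))

    eps0 = 23.0 + (26.0 + (21.448 - T * (46.8150 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))

    decl = math.asin(math.sin(eps) * math.sin(app_long))

    y = math.tan(eps / 2.0) ** 2
    L0r = math.radians(L0)
    eot_min = 4.0 * math.degrees(
        y * math.sin(2 * L0r)
        - 2 * e * math.sin(Mr)
        + 4 * e * y * math.sin(Mr) * math.cos(2 * L0r)
        - 0.5 * y * y * math.sin(4 * L0r)
        - 1.25 * e * e * math.sin(2 * Mr)
    )

    frac_day = (jd + 0.5) % 1.0  # fraction of the UTC day
    tst = (frac_day * 1440.0 + eot_min + 4.0 * location.lon) % 1440.0
    ha = tst / 4.0 - 180.0  # tst in [0, 1440) -> ha in [-180, 180)

    phi = math.radians(location.lat)
    har = math.radians(ha)
    cos_zen = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(har)
    cos_zen = max(-1.0, min(1.0, cos_zen))
    zen = math.acos(cos_zen)

    sin_zen = math.sin(zen)
    if sin_zen < 1e-9:  # sun at zenith/nadir: azimuth degenerate, pick 180
        return 180.0
    cos_az = (math.sin(phi) * cos_zen - math.sin(decl)) / (math.cos(phi) * sin_zen)
    cos_az = max(-1.0, min(1.0, cos_az))
    az = math.degrees(math.acos(cos_az))
    if ha > 0:
        return normalize_bearing(az + 180.0)
    return normalize_bearing(540.0 - az)
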