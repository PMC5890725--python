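"""Table readers/writers and GeoJSON export.

All interchange tables are comma-separated UTF-8 with a header row and
decimal points; coordinates are always WGS84 decimal degrees.  Timestamps in
files are civil date + time plus an explicit ``utc_offset`` column (hours);
they are converted to UTC on read.  Rows with unusable fields are counted
and skipped, never silently dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from .beelining import Beeline, BeelineObservation, FeederStation, NestEstimate, RangeDisc
from .dance import DanceRecord, NestSiteAdvert
from .density import CavityTreeRecord
from .geodesy import GeoPoint, destination_point

__all__ = [
    "BeelineTable",
    "read_beeline_table",
    "write_beeline_table",
    "read_dance_table",
    "write_dance_table",
    "dance_records_from_frame",
    "read_cavity_table",
    "write_cavity_table",
    "nests_to_geojson",
    "beelines_to_geojson",
    "adverts_to_geojson",
    "write_geojson",
]


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and not v.strip()


def _parse_time(date_s: str, time_s: str, utc_offset_h: float) -> datetime:
    t = datetime.fromisoformat(f"{str(date_s).strip()}T{str(time_s).strip()}")
    return (t - timedelta(hours=float(utc_offset_h))).replace(tzinfo=timezone.utc)


# --- beelining observations (raw-data schema) -------------------------------


@dataclass
class BeelineTable:
    """Parsed feeder stations and observations plus a skipped-row count."""

    feeders: list[FeederStation]
    observations: list[BeelineObservation]
    n_rows: int
    n_skipped: int

    @property
    def n_used(self) -> int:
        return self.n_rows - self.n_skipped


def read_beeline_table(path: str | Path) -> BeelineTable:
    """Read a beelining raw-data table.

    Required columns: ``feeder_id, lat, lon``; observation columns
    ``bee_id, round_trip_min, bearing_deg`` (either of the last two may be
    empty — such rows are kept and simply carry less information, but a row
    with neither is skipped).  Optional: ``site, date, time, hunt``.
    """
    df = pd.read_csv(path)
    required = {"feeder_id", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"beeline table missing columns: {sorted(missing)}")

    feeders: dict[str, FeederStation] = {}
    observations: list[BeelineObservation] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            fid = str(row["feeder_id"])
            if fid not in feeders:
                feeders[fid] = FeederStation(
                    id=fid,
                    location=GeoPoint(float(row["lat"]), float(row["lon"])),
                    site=str(row["site"]) if "site" in df.columns and not _is_missing(row.get("site")) else None,
                    hunt=str(row["hunt"]) if "hunt" in df.columns and not _is_missing(row.get("hunt")) else None,
                )
            trip = row.get("round_trip_min")
            bearing = row.get("bearing_deg")
            trip_ok = not _is_missing(trip)
            bearing_ok = not _is_missing(bearing)
            if not trip_ok and not bearing_ok:
                skipped += 1
                continue
            observations.append(
                BeelineObservation(
                    feeder_id=fid,
                    bee_id=str(row["bee_id"]) if not _is_missing(row.get("bee_id")) else None,
                    round_trip_min=float(trip) if trip_ok else None,
                    vanishing_bearing=float(bearing) if bearing_ok else None,
                )
            )
        except (ValueError, TypeError):
            skipped += 1
    return BeelineTable(list(feeders.values()), observations, len(df), skipped)


def write_beeline_table(
    feeders: Sequence[FeederStation],
    observations: Sequence[BeelineObservation],
    path: str | Path,
) -> None:
    by_id = {f.id: f for f in feeders}
    rows = []
    for o in observations:
        f = by_id[o.feeder_id]
        rows.append(
            {
                "feeder_id": o.feeder_id,
                "lat": round(f.location.lat, 6),
                "lon": round(f.location.lon, 6),
                "site": f.site or "",
                "hunt": f.hunt or "",
                "bee_id": o.bee_id or "",
                "round_trip_min": "" if o.round_trip_min is None else round(o.round_trip_min, 4),
                "bearing_deg": "" if o.vanishing_bearing is None else round(o.vanishing_bearing, 2),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# --- dance records (advertised-nest-sites schema) ---------------------------


def dance_records_from_frame(df: pd.DataFrame) -> list[DanceRecord]:
    """Build dance records from a table.

    Timestamp either as an ISO ``time_utc`` column, or ``date`` + ``time``
    plus ``utc_offset`` (hours, default 0).  Dance angles may be signed
    (±180) or compass-style [0, 360); both normalize identically.
    """
    required = {"swarm_id", "lat", "lon", "circuit_duration_s", "dance_angle_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dance table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        if "time_utc" in df.columns and not _is_missing(row.get("time_utc")):
            t = datetime.fromisoformat(str(row["time_utc"]))
            if t.tzinfo is None:
                t = t.replace(tzinfo=timezone.utc)
        else:
            offset = float(row["utc_offset"]) if "utc_offset" in df.columns else 0.0
            t = _parse_time(row["date"], row["time"], offset)
        records.append(
            DanceRecord(
                swarm_id=str(row["swarm_id"]),
                swarm_location=GeoPoint(float(row["lat"]), float(row["lon"])),
                time_utc=t,
                circuit_duration_s=float(row["circuit_duration_s"]),
                dance_angle_deg=float(row["dance_angle_deg"]),
                n_circuits=int(row["n_circuits"]) if "n_circuits" in df.columns and not _is_missing(row.get("n_circuits")) else None,
            )
        )
    return records


def read_dance_table(path: str | Path) -> list[DanceRecord]:
    return dance_records_from_frame(pd.read_csv(path))


def write_dance_table(records: Sequence[DanceRecord], path: str | Path) -> None:
    rows = [
        {
            "swarm_id": r.swarm_id,
            "lat": round(r.swarm_location.lat, 6),
            "lon": round(r.swarm_location.lon, 6),
            "time_utc": r.time_utc.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%S"),
            "circuit_duration_s": round(r.circuit_duration_s, 4),
            "dance_angle_deg": round(r.dance_angle_deg, 2),
            "n_circuits": r.n_circuits if r.n_circuits is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --- cavity-tree survey -----------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y", "ja"}


def read_cavity_table(path: str | Path) -> list[CavityTreeRecord]:
    """Read a cavity-tree survey table: ``tree_id, lat, lon, n_cavities, occupied``."""
    df = pd.read_csv(path)
    required = {"tree_id", "lat", "lon", "occupied"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cavity table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            CavityTreeRecord(
                tree_id=str(row["tree_id"]),
                location=GeoPoint(float(row["lat"]), float(row["lon"])),
                n_cavities=int(row["n_cavities"]) if "n_cavities" in df.columns else 1,
                occupied=str(row["occupied"]).strip().lower() in _TRUTHY,
            )
        )
    return records


def write_cavity_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["occupied"] = out["occupied"].map(lambda v: "yes" if v else "no")
    for col in ("lat", "lon"):
        out[col] = out[col].round(6)
    out.to_csv(path, index=False)


# --- GeoJSON ----------------------------------------------------------------


def _coords(p: GeoPoint) -> list[float]:
    return [round(p.lon, 6), round(p.lat, 6)]


def nests_to_geojson(estimates: Sequence[NestEstimate]) -> dict:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": _coords(e.location)},
            "properties": {
                "uncertainty_radius_m": round(e.uncertainty_radius, 1),
                "method": e.method,
                "supporting_feeders": list(e.supporting_feeders),
                "consistent": e.consistent,
            },
        }
        for e in estimates
    ]
    return {"type": "FeatureCollection", "features": features}


def beelines_to_geojson(constraints: Sequence[Beeline | RangeDisc]) -> dict:
    """Beelines as line segments and range discs as 64-gon polygons."""
    features = []
    for c in constraints:
        if isinstance(c, Beeline):
            tip = destination_point(c.origin, c.bearing, c.max_distance)
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [_coords(c.origin), _coords(tip)],
                    },
                    "properties": {
                        "kind": "beeline",
                        "feeder_id": c.feeder_id,
                        "bearing_deg": round(c.bearing, 2),
                        "max_distance_m": round(c.max_distance, 1),
                    },
                }
            )
        else:
            ring = [
                _coords(destination_point(c.center, az, c.radius))
                for az in range(0, 360, 6)
            ]
            ring.append(ring[0])
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "kind": "range-disc",
                        "feeder_id": c.feeder_id,
                        "radius_m": round(c.radius, 1),
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}


def adverts_to_geojson(adverts: Sequence[NestSiteAdvert]) -> dict:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": _coords(a.location)},
            "properties": {
                "swarm_id": a.swarm_id,
                "distance_m": round(a.distance, 1),
                "bearing_deg": round(a.bearing, 2),
            },
        }
        for a in adverts
    ]
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n", encoding="utf-8")
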