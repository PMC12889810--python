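"""Read, validate, filter and write per-trip GPS sequences.

A *trip* is one journey recorded as an ordered sequence of GPS points
(decimal-degree latitude/longitude, optional epoch timestamps) and is the
unit of classification throughout the package.  Two on-disk dialects are
supported:

* CSV — UTF-8, comma-separated, header
  ``trip_id,latitude,longitude,timestamp,label`` (timestamp and label
  columns optional); one row per point, point order = row order.
* GeoJSON — a ``FeatureCollection`` of ``LineString`` features carrying a
  ``trip_id`` property (optional ``label`` property); point order =
  coordinate order, coordinates stored GeoJSON-style as ``[lon, lat]``.

Coordinates are kept in raw decimal degrees; no projection is applied
before grid encoding, which discretizes latitude/longitude directly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

__all__ = [
    "GPSPoint",
    "Trip",
    "TripFilterConfig",
    "TripFormatError",
    "TripValidationError",
    "read_trips",
    "filter_trips",
    "write_trips",
]

Label = Literal["normal", "abnormal"]
VALID_LABELS = ("normal", "abnormal")

#: Default minimum trip length (number of GPS points); trips must be
#: strictly longer than this to survive filtering.
DEFAULT_ALPHA = 50


class TripFormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


class TripValidationError(ValueError):
    """Raised when trip contents violate a domain invariant."""


@dataclass(frozen=True)
class GPSPoint:
    """A single GPS fix in decimal degrees.

    ``timestamp`` is seconds since the epoch and optional: the grid
    encoding uses only spatial coordinates, temporal order being carried
    by sequence position.
    """

    latitude: float
    longitude: float
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise TripValidationError(
                f"latitude {self.latitude} outside [-90, 90]"
            )
        if not (-180.0 <= self.longitude <= 180.0):
            raise TripValidationError(
                f"longitude {self.longitude} outside [-180, 180]"
            )


@dataclass
class Trip:
    """Ordered sequence of GPS points for one journey, with optional label."""

    trip_id: str
    points: list[GPSPoint]
    label: Optional[Label] = None

    def __post_init__(self) -> None:
        if not self.points:
            raise TripValidationError(f"trip {self.trip_id!r} has no points")
        if self.label is not None and self.label not in VALID_LABELS:
            raise TripValidationError(
                f"trip {self.trip_id!r}: label {self.label!r} not in {VALID_LABELS}"
            )
        ts = [p.timestamp for p in self.points if p.timestamp is not None]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise TripValidationError(
                f"trip {self.trip_id!r}: timestamps not non-decreasing"
            )

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class TripFilterConfig:
    """Minimum-length filter: keep trips with strictly more than ``alpha`` points."""

    alpha: int = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise TripValidationError(f"alpha must be >= 1, got {self.alpha}")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _coerce_label(raw) -> Optional[Label]:
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    s = str(raw).strip()
    if not s:
        return None
    if s not in VALID_LABELS:
        raise TripValidationError(f"unknown label {s!r}; expected one of {VALID_LABELS}")
    return s  # type: ignore[return-value]


def _read_csv(path: Path) -> list[Trip]:
    df = pd.read_csv(path, dtype={"trip_id": str})
    required = ("trip_id", "latitude", "longitude")
    for col in required:
        if col not in df.columns:
            raise TripFormatError(f"{path}: missing required column {col!r}")
    has_ts = "timestamp" in df.columns
    has_label = "label" in df.columns

    trips: list[Trip] = []
    # sort=False preserves first-appearance order of trip_ids; rows within a
    # group keep file order.
    for trip_id, group in df.groupby("trip_id", sort=False):
        points = []
        label: Optional[Label] = None
        for row_idx, row in enumerate(group.itertuples(index=False)):
            lat, lon = float(row.latitude), float(row.longitude)
            ts = None
            if has_ts and not pd.isna(row.timestamp):
                ts = float(row.timestamp)
            try:
                points.append(GPSPoint(lat, lon, ts))
            except TripValidationError as exc:
                raise TripValidationError(
                    f"{path}: trip {trip_id!r}, row {row_idx}: {exc}"
                ) from exc
        if has_label:
            labels = {
                _coerce_label(v) for v in group["label"].tolist()
            } - {None}
            if len(labels) > 1:
                raise TripValidationError(
                    f"{path}: trip {trip_id!r} carries conflicting labels {sorted(labels)}"
                )
            label = labels.pop() if labels else None
        trips.append(Trip(str(trip_id), points, label))
    return trips


def _read_geojson(path: Path) -> list[Trip]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise TripFormatError(f"{path}: expected a GeoJSON FeatureCollection")
    trips: list[Trip] = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise TripFormatError(
                f"{path}: every feature must be a LineString, got {geom.get('type')!r}"
            )
        props = feat.get("properties") or {}
        if "trip_id" not in props:
            raise TripFormatError(f"{path}: feature missing required property 'trip_id'")
        trip_id = str(props["trip_id"])
        points = []
        for i, coord in enumerate(geom.get("coordinates", [])):
            lon, lat = coord[0], coord[1]  # GeoJSON order is [lon, lat]
            ts = coord[2] if len(coord) > 2 else None
            try:
                points.append(GPSPoint(float(lat), float(lon), ts))
            except TripValidationError as exc:
                raise TripValidationError(
                    f"{path}: trip {trip_id!r}, coordinate {i}: {exc}"
                ) from exc
        trips.append(Trip(trip_id, points, _coerce_label(props.get("label"))))
    return trips


def read_trips(path: str | Path, format: Literal["csv", "geojson"] = "csv") -> list[Trip]:
    """Read trips from ``path`` in the given dialect.

    Returns one :class:`Trip` per distinct ``trip_id``, preserving point
    order (CSV row order, or LineString coordinate order).  Labels are
    attached when a ``label`` column/property is present.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "geojson":
        return _read_geojson(path)
    raise TripFormatError(f"unknown format {format!r}; expected 'csv' or 'geojson'")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_trips(trips: Sequence[Trip], config: TripFilterConfig) -> list[Trip]:
    """Keep exactly the trips with point count strictly greater than alpha.

    Order is preserved; the operation is idempotent.
    """
    return [t for t in trips if len(t.points) > config.alpha]


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

# 7 decimal places of a degree is ~1.1 cm at the equator — beyond GPS noise.
_COORD_FMT = "%.7f"


def _write_csv(trips: Iterable[Trip], path: Path) -> None:
    rows = []
    for trip in trips:
        for p in trip.points:
            rows.append(
                {
                    "trip_id": trip.trip_id,
                    "latitude": p.latitude,
                    "longitude": p.longitude,
                    "timestamp": p.timestamp,
                    "label": trip.label,
                }
            )
    df = pd.DataFrame(
        rows, columns=["trip_id", "latitude", "longitude", "timestamp", "label"]
    )
    df.to_csv(path, index=False, float_format=_COORD_FMT)


def _write_geojson(trips: Iterable[Trip], path: Path) -> None:
    features = []
    for trip in trips:
        coords = [
            [round(p.longitude, 7), round(p.latitude, 7)]
            if p.timestamp is None
            else [round(p.longitude, 7), round(p.latitude, 7), p.timestamp]
            for p in trip.points
        ]
        props: dict = {"trip_id": trip.trip_id}
        if trip.label is not None:
            props["label"] = trip.label
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": props,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_trips(
    trips: Sequence[Trip], path: str | Path, format: Literal["csv", "geojson"] = "csv"
) -> None:
    """Write trips to ``path``; ``read_trips`` on the result round-trips
    trip ids, point order, labels, and coordinates to 7 decimal places."""
    path = Path(path)
    if format == "csv":
        _write_csv(trips, path)
    elif format == "geojson":
        _write_geojson(trips, path)
    else:
        raise TripFormatError(f"unknown format {format!r}; expected 'csv' or 'geojson'")
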