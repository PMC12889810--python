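"""Trajectory-to-image transformation: binary occupancy grids.

Each trip is rendered into a fixed-size H×W binary matrix G where
``G[i, j] = 1`` iff at least one GPS point of the trip falls inside cell
``(i, j)``.  Discretization uses the trip's *own* bounding box
(trip-specific normalization), so the encoding is translation- and
scale-invariant per trip: a trip's grid depends only on the shape of the
trajectory, not on where on Earth it was driven or how large it is.

Conventions (all downstream stages — rotation augmentation, patch
embedding, PNG export — rely on these):

* row 0 is the *southernmost* row (min latitude), column 0 the
  *westernmost* column (min longitude);
* cells are half-open intervals ``[k·c, (k+1)·c)`` with the final cell
  closed, so points on the max boundary land in row ``H-1`` / col ``W-1``;
* latitude and longitude spans are scaled independently to fill H and W
  (aspect ratio is NOT preserved);
* a zero-span axis (single point, or exactly east-west / north-south
  trips) is expanded to a span of 1e-9 degrees before discretization by
  lowering its minimum, which pins the points to the last (max-side)
  cell; expanding on the min side keeps the assignment exact in floating
  point, so the translation/scale invariances hold bit-for-bit even for
  degenerate trips;
* PNG export flips vertically so north appears at the top of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .trajectory_io import Trip, TripValidationError

__all__ = [
    "BoundingBox",
    "GridSpec",
    "BinaryGrid",
    "compute_bounding_box",
    "assign_cell",
    "encode_trip",
    "encode_trips",
    "grid_to_png",
    "png_to_grid",
]

#: Total span assigned to a degenerate (zero-width) bounding-box axis.
DEGENERATE_SPAN_EPS = 1e-9


@dataclass(frozen=True)
class BoundingBox:
    min_lat: float
    max_lat: float
    min_lon: float
    max_lon: float

    def __post_init__(self) -> None:
        if self.min_lat > self.max_lat or self.min_lon > self.max_lon:
            raise ValueError(f"inverted bounding box: {self}")

    def contains(self, lat: float, lon: float) -> bool:
        return (
            self.min_lat <= lat <= self.max_lat
            and self.min_lon <= lon <= self.max_lon
        )


@dataclass(frozen=True)
class GridSpec:
    """Grid resolution.  The per-trip cell size is derived from the
    bounding box: ``cell_height = lat_span / H``, ``cell_width = lon_span / W``."""

    H: int = 128
    W: int = 128

    def __post_init__(self) -> None:
        if self.H < 1 or self.W < 1:
            raise ValueError(f"grid resolution must be >= 1, got {self.H}x{self.W}")

    def cell_size(self, box: BoundingBox) -> tuple[float, float]:
        return (
            (box.max_lat - box.min_lat) / self.H,
            (box.max_lon - box.min_lon) / self.W,
        )


@dataclass
class BinaryGrid:
    """H×W occupancy matrix over {0, 1} — the trip's image representation."""

    values: np.ndarray  # uint8, shape (H, W)
    spec: GridSpec
    trip_id: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (self.spec.H, self.spec.W):
            raise ValueError(
                f"grid shape {self.values.shape} != spec {(self.spec.H, self.spec.W)}"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("grid values must be in {0, 1}")

    def popcount(self) -> int:
        return int(self.values.sum())


def compute_bounding_box(trip: Trip) -> BoundingBox:
    """Coordinate-wise min/max over all points of the trip."""
    if not trip.points:
        raise TripValidationError(f"trip {trip.trip_id!r} is empty")
    lats = np.fromiter((p.latitude for p in trip.points), dtype=float)
    lons = np.fromiter((p.longitude for p in trip.points), dtype=float)
    return BoundingBox(lats.min(), lats.max(), lons.min(), lons.max())


def _expand_degenerate(box: BoundingBox) -> BoundingBox:
    # Expand on the min side only: the points then sit exactly on the max
    # boundary and clamp into the last cell.  A symmetric expansion would
    # center them on the cell boundary H/2, where rounding after a
    # translation can flip the assigned cell.
    min_lat, max_lat = box.min_lat, box.max_lat
    min_lon, max_lon = box.min_lon, box.max_lon
    if max_lat == min_lat:
        min_lat = min_lat - DEGENERATE_SPAN_EPS
    if max_lon == min_lon:
        min_lon = min_lon - DEGENERATE_SPAN_EPS
    return BoundingBox(min_lat, max_lat, min_lon, max_lon)


def assign_cell(
    point, box: BoundingBox, spec: GridSpec
) -> tuple[int, int]:
    """Map a point inside ``box`` to its (row, col) cell.

    Half-open cells with the last cell closed: points exactly on the max
    boundary clamp into row ``H-1`` / col ``W-1``.
    """
    lat, lon = point.latitude, point.longitude
    if not box.contains(lat, lon):
        raise ValueError(
            f"point ({lat}, {lon}) lies outside bounding box {box}"
        )
    box = _expand_degenerate(box)
    cell_h, cell_w = spec.cell_size(box)
    row = min(int((lat - box.min_lat) / cell_h), spec.H - 1)
    col = min(int((lon - box.min_lon) / cell_w), spec.W - 1)
    return row, col


def encode_trip(trip: Trip, spec: GridSpec = GridSpec()) -> BinaryGrid:
    """Encode a trip as a binary occupancy grid over its own bounding box."""
    box = _expand_degenerate(compute_bounding_box(trip))
    lats = np.fromiter((p.latitude for p in trip.points), dtype=float)
    lons = np.fromiter((p.longitude for p in trip.points), dtype=float)
    cell_h, cell_w = spec.cell_size(box)
    rows = np.minimum(((lats - box.min_lat) / cell_h).astype(int), spec.H - 1)
    cols = np.minimum(((lons - box.min_lon) / cell_w).astype(int), spec.W - 1)
    values = np.zeros((spec.H, spec.W), dtype=np.uint8)
    values[rows, cols] = 1
    return BinaryGrid(values, spec, trip.trip_id, trip.label)


def encode_trips(trips, spec: GridSpec = GridSpec()) -> list[BinaryGrid]:
    return [encode_trip(t, spec) for t in trips]


def grid_to_png(grid: BinaryGrid, path: str | Path, invert: bool = False) -> None:
    """Write the grid as a 1-bit PNG, visited cells white on black by
    default, north (max latitude) at the top of the image."""
    img_rows = np.flipud(grid.values)  # image row 0 = northernmost
    pixels = (1 - img_rows) if invert else img_rows
    Image.fromarray((pixels * 255).astype(np.uint8), mode="L").convert("1").save(
        Path(path)
    )


def png_to_grid(
    path: str | Path,
    trip_id: str = "",
    label: Optional[str] = None,
    invert: bool = False,
) -> BinaryGrid:
    """Inverse of :func:`grid_to_png` (up to trip metadata)."""
    img = np.asarray(Image.open(Path(path)).convert("L"))
    pixels = (img > 127).astype(np.uint8)
    if invert:
        pixels = 1 - pixels
    values = np.flipud(pixels)
    return BinaryGrid(values, GridSpec(*values.shape), trip_id, label)
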