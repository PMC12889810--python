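"""Synthetic GPS trip simulator.

Generates labeled trips whose abnormal class exhibits the behavioral
signatures of disoriented driving — repeated path selections, cyclic
driving patterns, and long-distance U-turns — so that every downstream
stage (encoding, augmentation, training, evaluation) can be exercised on
data with known ground truth.

Normal trips are correlated random walks: a heading that drifts with
Gaussian noise and occasionally takes a 90°-family turn, as a driver
following a road network would, without deliberately revisiting prior
locations.  Abnormal trips are explicit geometric programs:

* ``cycle`` — ``n_loops`` closed circuits around a waypoint;
* ``repeated_segment`` — the same sub-path traversed three times
  (out, back, out again);
* ``long_uturn`` — a forward leg, a reversal, and a retrace of a large
  fraction of the forward leg.

Retraced passes carry a small lateral (lane) offset, as real return
traffic does: without it a retrace revisits exactly the same cells and a
*binary* occupancy grid — which records visits, not visit counts — would
erase the behavior entirely.  The offset is what makes U-turns and
repeated segments visible as parallel tracks in the image
representation, and it still registers as revisitation in the
run-based :func:`cell_revisit_ratio` statistic because offsets are
sub-cell along the dominant axis.

All generators are deterministic given their seed.  Per-trip seeds in a
cohort are derived from the master seed by a counter-keyed
``SeedSequence`` so inserting a trip never reshuffles the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .grid_encoding import GridSpec, compute_bounding_box, _expand_degenerate
from .trajectory_io import GPSPoint, Trip

__all__ = [
    "SimConfig",
    "ABNORMAL_PATTERNS",
    "generate_normal_trip",
    "generate_abnormal_trip",
    "generate_cohort",
    "cell_revisit_ratio",
]

ABNORMAL_PATTERNS = ("cycle", "repeated_segment", "long_uturn")

#: Default pattern mix for cohorts: equal weight on the three behaviors.
DEFAULT_MIX = {p: 1.0 / 3.0 for p in ABNORMAL_PATTERNS}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a single simulated trip.

    ``step_deg`` is the nominal per-step displacement in decimal degrees;
    the default 1e-4° is roughly 11 m, a plausible 1 Hz urban GPS spacing.
    ``heading_noise_sd`` (radians) controls how wiggly trajectories are and
    is the main knob for hardening the classification task.  ``turn_prob``
    is the per-step probability of a 90°-family turn in normal driving.
    ``lane_offset_steps`` is the lateral offset between retraced passes of
    U-turn / repeated-segment trips, in units of ``step_deg`` (~a road
    width at the default step).
    """

    n_points: int = 600
    step_deg: float = 1e-4
    heading_noise_sd: float = 0.08
    turn_prob: float = 0.01
    lane_offset_steps: float = 2.0
    # 600 points ~ a 10-minute trip at 1 Hz; step 1e-4 deg ~ 11 m at 40 km/h.
    origin_lat: float = 26.35
    origin_lon: float = -80.10
    abnormal_pattern: str = "cycle"
    n_loops: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.step_deg <= 0:
            raise ValueError(f"step_deg must be > 0, got {self.step_deg}")
        if self.heading_noise_sd < 0:
            raise ValueError("heading_noise_sd must be >= 0")
        if self.n_loops < 1:
            raise ValueError("n_loops must be >= 1")


def _to_trip(
    xy: np.ndarray, config: SimConfig, trip_id: str, label: Optional[str]
) -> Trip:
    # xy column 0 = east offset (degrees lon), column 1 = north offset (lat)
    points = [
        GPSPoint(config.origin_lat + float(y), config.origin_lon + float(x), float(i))
        for i, (x, y) in enumerate(xy)
    ]
    return Trip(trip_id, points, label)


def _random_walk(
    n: int, rng: np.random.Generator, config: SimConfig, heading0: float
) -> np.ndarray:
    """Correlated random walk: piecewise-constant heading with Gaussian
    drift and occasional ±90°/180°-family turns."""
    heading = heading0
    steps = np.empty((n - 1, 2))
    for i in range(n - 1):
        if config.turn_prob > 0 and rng.random() < config.turn_prob:
            heading += rng.choice((-np.pi / 2, np.pi / 2))
        if config.heading_noise_sd > 0:
            heading += rng.normal(0.0, config.heading_noise_sd)
        steps[i] = (math.cos(heading), math.sin(heading))
    xy = np.zeros((n, 2))
    xy[1:] = np.cumsum(steps * config.step_deg, axis=0)
    return xy


def generate_normal_trip(config: SimConfig, trip_id: str = "normal-0") -> Trip:
    """A correlated random walk that does not deliberately revisit prior
    locations.  Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    heading0 = rng.uniform(0.0, 2.0 * np.pi)
    xy = _random_walk(config.n_points, rng, config, heading0)
    return _to_trip(xy, config, trip_id, "normal")


def _cycle_pattern(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    # Radius chosen so n_loops full circumferences consume the point budget
    # at the nominal step length; first and last point coincide (mod noise).
    n = config.n_points
    radius = n * config.step_deg / (2.0 * np.pi * config.n_loops)
    theta = np.linspace(0.0, 2.0 * np.pi * config.n_loops, n)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    xy = radius * np.column_stack(
        (np.cos(theta + phase) - math.cos(phase), np.sin(theta + phase) - math.sin(phase))
    )
    if config.heading_noise_sd > 0:
        jitter_sd = config.heading_noise_sd * config.step_deg
        xy = xy + rng.normal(0.0, jitter_sd, size=xy.shape)
    return xy


def _lane_perp(xy: np.ndarray, config: SimConfig) -> np.ndarray:
    """Unit vector perpendicular to the path's overall direction, scaled
    to one lane offset."""
    d = xy[-1] - xy[0]
    norm = float(np.hypot(*d))
    if norm == 0.0:
        d, norm = np.array([1.0, 0.0]), 1.0
    return np.array([-d[1], d[0]]) / norm * config.lane_offset_steps * config.step_deg


def _repeated_segment_pattern(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    # Traverse the same base sub-path out, back, and out again (3 passes).
    # Return passes ride one lane over, so forward passes revisit the same
    # cells while the return pass paints a visible parallel track.
    n = config.n_points
    passes = 3
    m = n // passes + 1
    base_cfg = replace(config, heading_noise_sd=min(config.heading_noise_sd, 0.08))
    heading0 = rng.uniform(0.0, 2.0 * np.pi)
    base = _random_walk(m, rng, base_cfg, heading0)
    perp = _lane_perp(base, config)
    path = [base]
    forward = False
    while sum(len(p) for p in path) < n:
        nxt = base[::-1] + perp if not forward else base
        path.append(nxt[1:])  # skip the shared endpoint
        forward = not forward
    xy = np.concatenate(path)[:n]
    if config.heading_noise_sd > 0:
        jitter_sd = 0.3 * config.heading_noise_sd * config.step_deg
        xy = xy + rng.normal(0.0, jitter_sd, size=xy.shape)
    return xy


def _long_uturn_pattern(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    # Forward leg, reversal, then retrace of >= 25% of the forward leg
    # (default retraces ~40% of the trip's points) one lane over.
    n = config.n_points
    n_back = max(2, int(round(0.4 * n)))
    n_fwd = n - n_back + 1
    fwd_cfg = replace(config, turn_prob=0.0)
    heading0 = rng.uniform(0.0, 2.0 * np.pi)
    fwd = _random_walk(n_fwd, rng, fwd_cfg, heading0)
    back = fwd[::-1][1 : n_back + 1] + _lane_perp(fwd, config)
    xy = np.concatenate([fwd, back])[:n]
    if config.heading_noise_sd > 0:
        jitter_sd = 0.3 * config.heading_noise_sd * config.step_deg
        xy = xy + rng.normal(0.0, jitter_sd, size=xy.shape)
    return xy


_PATTERN_FNS = {
    "cycle": _cycle_pattern,
    "repeated_segment": _repeated_segment_pattern,
    "long_uturn": _long_uturn_pattern,
}


def generate_abnormal_trip(config: SimConfig, trip_id: str = "abnormal-0") -> Trip:
    """An abnormal trip realizing ``config.abnormal_pattern``; labeled
    ``abnormal`` and deterministic given ``config.seed``."""
    if config.abnormal_pattern not in _PATTERN_FNS:
        raise ValueError(
            f"unknown abnormal pattern {config.abnormal_pattern!r}; "
            f"expected one of {ABNORMAL_PATTERNS}"
        )
    rng = np.random.default_rng(config.seed)
    xy = _PATTERN_FNS[config.abnormal_pattern](config, rng)
    return _to_trip(xy, config, trip_id, "abnormal")


def _trip_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    # Counter-keyed derivation: trip i's stream depends only on (seed, i).
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def generate_cohort(
    n_normal: int,
    n_abnormal: int,
    mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    base_config: SimConfig = SimConfig(),
) -> list[Trip]:
    """Generate a labeled cohort of ``n_normal + n_abnormal`` trips.

    Abnormal patterns are drawn from ``mix`` (a distribution over
    pattern names, default uniform).  Origins are jittered per trip so
    bounding boxes differ across the cohort.  Reproducible given ``seed``.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("cohort counts must be >= 0")
    mix = dict(mix or DEFAULT_MIX)
    bad = set(mix) - set(ABNORMAL_PATTERNS)
    if bad:
        raise ValueError(f"unknown abnormal patterns in mix: {sorted(bad)}")
    names = sorted(mix)
    weights = np.array([mix[k] for k in names], dtype=float)
    if n_abnormal > 0 and (weights.sum() <= 0 or (weights < 0).any()):
        raise ValueError("mix must be a non-negative distribution")

    trips: list[Trip] = []
    for i in range(n_normal + n_abnormal):
        rng = np.random.default_rng(_trip_seed(seed, i))
        trip_seed = int(rng.integers(0, 2**31 - 1))
        jitter = rng.uniform(-0.05, 0.05, size=2)
        cfg = replace(
            base_config,
            seed=trip_seed,
            origin_lat=base_config.origin_lat + float(jitter[0]),
            origin_lon=base_config.origin_lon + float(jitter[1]),
        )
        if i < n_normal:
            trips.append(generate_normal_trip(cfg, trip_id=f"trip-{i:05d}"))
        else:
            pattern = names[
                int(rng.choice(len(names), p=weights / weights.sum()))
            ]
            cfg = replace(cfg, abnormal_pattern=pattern)
            trips.append(generate_abnormal_trip(cfg, trip_id=f"trip-{i:05d}"))
    return trips


def hardened_config(base: SimConfig = SimConfig()) -> SimConfig:
    """A noisier, less separable variant of the default conditions.

    Extra heading noise and turn frequency blur (but do not erase) the
    loop/retrace structure at the grid scale; abnormal trips remain
    recognizable in principle while normal trips start to self-overlap,
    which is the regime where training-data quantity and augmentation
    matter.  Noise far beyond this collapses U-turn trips into the same
    scribbles as normal ones and the labels become irreducibly ambiguous.
    """
    return replace(base, heading_noise_sd=0.25, turn_prob=0.05, n_loops=2)


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

def cell_revisit_ratio(
    trip: Trip, spec: GridSpec = GridSpec(64, 64), min_separation: int = 1
) -> float:
    """Fraction of visited grid cells entered in >= 2 distinct visit runs.

    A *visit run* is a maximal block of consecutive point indices mapping
    to the same cell; a cell counts as revisited when two of its runs
    start more than ``min_separation`` indices apart.  Consecutive fixes
    sitting in one cell therefore do not count as a revisit, while loops,
    retraced segments and U-turns do.
    """
    box = _expand_degenerate(compute_bounding_box(trip))
    cell_h, cell_w = spec.cell_size(box)
    lats = np.array([p.latitude for p in trip.points])
    lons = np.array([p.longitude for p in trip.points])
    rows = np.minimum(((lats - box.min_lat) / cell_h).astype(int), spec.H - 1)
    cols = np.minimum(((lons - box.min_lon) / cell_w).astype(int), spec.W - 1)
    run_starts: dict[tuple[int, int], list[int]] = {}
    prev = None
    for i, cell in enumerate(zip(rows.tolist(), cols.tolist())):
        if cell != prev:
            run_starts.setdefault(cell, []).append(i)
        prev = cell
    revisited = sum(
        1
        for starts in run_starts.values()
        if len(starts) >= 2 and (starts[-1] - starts[0]) > min_separation
    )
    return revisited / len(run_starts)
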