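"""Model-ready dataset assembly: stacking, rotational augmentation, splits.

Binary grids are stacked into an ``N x 1 x H x W`` tensor with parallel
label / trip-id / provenance vectors.  Class imbalance is addressed by
rotating minority-class grids through 90°/180°/270° — lattice rotations
preserve the spatial structure of a trip while varying its orientation,
and are applied to the training split only.  Splits are stratified by
label, and rotated copies always follow their source trip so no
augmented view of a test trip can leak into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .grid_encoding import BinaryGrid, GridSpec

__all__ = [
    "LABEL_TO_INDEX",
    "INDEX_TO_LABEL",
    "GridDataset",
    "rotate_grid",
    "augment_minority",
    "stack_dataset",
    "split_dataset",
    "save_dataset",
    "load_dataset",
]

LABEL_TO_INDEX = {"normal": 0, "abnormal": 1}
INDEX_TO_LABEL = {v: k for k, v in LABEL_TO_INDEX.items()}

PROVENANCES = ("original", "rot90", "rot180", "rot270")
_ANGLE_TO_PROVENANCE = {90: "rot90", 180: "rot180", 270: "rot270"}


@dataclass
class GridDataset:
    """Stack of N single-channel binary grids with labels and provenance."""

    grids: np.ndarray       # uint8, shape (N, 1, H, W)
    labels: np.ndarray      # int64, shape (N,), values in {0, 1}
    trip_ids: np.ndarray    # str, shape (N,)
    provenance: np.ndarray  # str, shape (N,), values in PROVENANCES

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.trip_ids = np.asarray(self.trip_ids, dtype=str)
        self.provenance = np.asarray(self.provenance, dtype=str)
        if self.grids.ndim != 4 or self.grids.shape[1] != 1:
            raise ValueError(f"grids must have shape (N, 1, H, W), got {self.grids.shape}")
        n = len(self.grids)
        for name, vec in (
            ("labels", self.labels),
            ("trip_ids", self.trip_ids),
            ("provenance", self.provenance),
        ):
            if len(vec) != n:
                raise ValueError(f"{name} has length {len(vec)}, expected {n}")

    def __len__(self) -> int:
        return len(self.grids)

    @property
    def resolution(self) -> tuple[int, int]:
        return self.grids.shape[2], self.grids.shape[3]

    def class_counts(self) -> dict[int, int]:
        return {int(c): int(n) for c, n in zip(*np.unique(self.labels, return_counts=True))}

    def subset(self, idx: np.ndarray) -> "GridDataset":
        return GridDataset(
            self.grids[idx], self.labels[idx], self.trip_ids[idx], self.provenance[idx]
        )


def rotate_grid(grid: BinaryGrid, angle: int) -> BinaryGrid:
    """Exact counterclockwise lattice rotation of a grid about its center.

    90° and 270° require a square grid.  Bit count, label and trip id are
    preserved; only the orientation changes.
    """
    if angle not in (90, 180, 270):
        raise ValueError(f"angle must be one of 90, 180, 270; got {angle}")
    H, W = grid.values.shape
    if angle in (90, 270) and H != W:
        raise ValueError(f"90/270 rotation requires a square grid, got {H}x{W}")
    rotated = np.rot90(grid.values, k=angle // 90).copy()
    spec = GridSpec(*rotated.shape)
    return BinaryGrid(rotated, spec, grid.trip_id, grid.label)


def stack_dataset(
    grids: Sequence[BinaryGrid], resolution: Optional[tuple[int, int]] = None
) -> GridDataset:
    """Order-preserving stack of labeled grids with a channel dimension.

    ``resolution`` is required only for stacking an empty list.
    """
    if not grids:
        if resolution is None:
            raise ValueError("resolution must be given when stacking an empty list")
        H, W = resolution
        return GridDataset(
            np.zeros((0, 1, H, W), dtype=np.uint8),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=str),
            np.zeros(0, dtype=str),
        )
    shapes = {g.values.shape for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"mixed grid resolutions: {sorted(shapes)}")
    missing = [g.trip_id for g in grids if g.label is None]
    if missing:
        raise ValueError(f"unlabeled grids cannot be stacked: {missing[:5]}")
    return GridDataset(
        np.stack([g.values for g in grids])[:, None, :, :],
        np.array([LABEL_TO_INDEX[g.label] for g in grids], dtype=np.int64),
        np.array([g.trip_id for g in grids], dtype=str),
        np.array(["original"] * len(grids), dtype=str),
    )


def augment_minority(
    dataset: GridDataset, angles: Iterable[int] = (90, 180, 270)
) -> GridDataset:
    """Append one rotated copy per (minority-class sample, angle).

    Original samples are retained unchanged and the majority class is
    untouched.  The minority class is the label with the smaller count;
    ties break toward the abnormal class, the clinically relevant
    minority.  Intended for the training split only.
    """
    angles = sorted(set(angles))
    bad = [a for a in angles if a not in (90, 180, 270)]
    if bad:
        raise ValueError(f"angles must be among 90/180/270, got {bad}")
    counts = dataset.class_counts()
    if len(counts) < 2:
        raise ValueError(
            f"augment_minority needs two classes, found labels {sorted(counts)}"
        )
    H, W = dataset.resolution
    if H != W and any(a in (90, 270) for a in angles):
        raise ValueError("90/270 rotation requires square grids")
    # tie toward abnormal (=1)
    minority = 1 if counts[1] <= counts[0] else 0
    idx = np.flatnonzero(dataset.labels == minority)

    extra_grids, extra_labels, extra_ids, extra_prov = [], [], [], []
    for angle in angles:
        k = angle // 90
        rotated = np.rot90(dataset.grids[idx], k=k, axes=(2, 3))
        extra_grids.append(rotated)
        extra_labels.append(dataset.labels[idx])
        extra_ids.append(dataset.trip_ids[idx])
        extra_prov.append(np.full(len(idx), _ANGLE_TO_PROVENANCE[angle]))
    return GridDataset(
        np.concatenate([dataset.grids, *extra_grids]),
        np.concatenate([dataset.labels, *extra_labels]),
        np.concatenate([dataset.trip_ids, *extra_ids]),
        np.concatenate([dataset.provenance, *extra_prov]),
    )


def split_dataset(
    dataset: GridDataset, test_fraction: float, seed: int
) -> tuple[GridDataset, GridDataset]:
    """Stratified train/test split, reproducible given ``seed``.

    Splitting is at trip level: all samples sharing a ``trip_id``
    (original plus any rotated copies) land in the same split, so
    augmented views never straddle the boundary.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)

    # one label per trip (rotated copies share their source's label)
    trip_label: dict[str, int] = {}
    order: list[str] = []
    for tid, lab in zip(dataset.trip_ids.tolist(), dataset.labels.tolist()):
        if tid not in trip_label:
            trip_label[tid] = lab
            order.append(tid)

    test_trips: set[str] = set()
    for label in sorted(set(trip_label.values())):
        members = [t for t in order if trip_label[t] == label]
        if len(members) < 2:
            raise ValueError(
                f"class {INDEX_TO_LABEL.get(label, label)} has {len(members)} trip(s); "
                "need >= 2 to split"
            )
        n_test = int(round(test_fraction * len(members)))
        n_test = min(max(n_test, 1), len(members) - 1)
        picked = rng.choice(len(members), size=n_test, replace=False)
        test_trips.update(members[i] for i in picked)

    in_test = np.array([t in test_trips for t in dataset.trip_ids.tolist()])
    return dataset.subset(~in_test), dataset.subset(in_test)


def save_dataset(dataset: GridDataset, path: str | Path) -> None:
    """Persist the stack and its parallel vectors in a compressed ``.npz``."""
    np.savez_compressed(
        Path(path),
        grids=dataset.grids,
        labels=dataset.labels,
        trip_ids=dataset.trip_ids,
        provenance=dataset.provenance,
    )


def load_dataset(path: str | Path) -> GridDataset:
    with np.load(Path(path), allow_pickle=False) as npz:
        return GridDataset(
            npz["grids"], npz["labels"], npz["trip_ids"], npz["provenance"]
        )
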