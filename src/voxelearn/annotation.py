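"""Sparse stroke annotations: rasterisation, the tagged-voxel store, and the
training table.

A stroke is a polyline with a radius, swept through the volume; every voxel
whose centre lies within ``radius`` of the polyline receives the stroke's
label.  Tags carry an iteration number so that later correction rounds can
overwrite earlier labels; the full event log is retained so a correction
history can be audited.

Voxel IDs follow a single documented linearisation, x fastest::

    voxel_id = x + nx * (y + ny * z)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError, SchemaError

POSITIVE = "positive"
NEGATIVE = "negative"
_LABELS = (POSITIVE, NEGATIVE)


def xyz_to_id(x: int, y: int, z: int, dims: Sequence[int]) -> int:
    """Linear voxel ID for integer coordinates (x fastest)."""
    nx, ny, nz = dims
    return int(x) + nx * (int(y) + ny * int(z))


def id_to_xyz(voxel_id: int, dims: Sequence[int]) -> tuple[int, int, int]:
    """Inverse of :func:`xyz_to_id`."""
    nx, ny, _ = dims
    x = voxel_id % nx
    y = (voxel_id // nx) % ny
    z = voxel_id // (nx * ny)
    return int(x), int(y), int(z)


def _check_ids(voxel_ids: Iterable[int], dims: Sequence[int]) -> list[int]:
    nx, ny, nz = dims
    n = nx * ny * nz
    ids = [int(v) for v in voxel_ids]
    for v in ids:
        if not 0 <= v < n:
            raise ValidationError(f"voxel id {v} out of bounds for dims {tuple(dims)}")
    return ids


@dataclass(frozen=True)
class Stroke:
    """A labelled polyline swept with a spherical brush.

    Parameters
    ----------
    polyline : sequence of (x, y, z) points in voxel coordinates.
    radius : brush radius in voxel units, >= 0.
    label : ``"positive"`` or ``"negative"``.
    """

    polyline: tuple[tuple[float, float, float], ...]
    radius: float
    label: str

    def __post_init__(self):
        pts = tuple(tuple(float(c) for c in p) for p in self.polyline)
        if len(pts) == 0:
            raise ValidationError("stroke polyline must contain at least one point")
        if not np.isfinite(self.radius) or self.radius < 0:
            raise ValidationError("stroke radius must be finite and >= 0")
        if self.label not in _LABELS:
            raise ValidationError(f"label must be one of {_LABELS}, got {self.label!r}")
        object.__setattr__(self, "polyline", pts)


@dataclass(frozen=True)
class VoxelTag:
    voxel_id: int
    label: str  # "positive" | "negative"
    iteration: int


@dataclass
class _Event:
    kind: str  # "add" | "erase"
    voxel_ids: tuple[int, ...]
    label: str | None
    iteration: int


def _segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each row of ``points`` to segment a->b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def stroke_to_voxels(stroke: Stroke, dims: Sequence[int]) -> set[int]:
    """Rasterise a stroke: IDs of all in-bounds voxels whose centre lies
    within ``stroke.radius`` of the polyline (exact point-to-segment
    distance).  Voxels falling outside the volume are clipped.
    """
    nx, ny, nz = (int(d) for d in dims)
    if min(nx, ny, nz) < 1:
        raise ValidationError("dims must be positive")
    pts = np.asarray(stroke.polyline, dtype=float)
    r = float(stroke.radius)

    lo = np.maximum(np.floor(pts.min(axis=0) - r), 0).astype(int)
    hi = np.minimum(np.ceil(pts.max(axis=0) + r), np.array([nx, ny, nz]) - 1).astype(int)
    if np.any(hi < lo):
        return set()
    xs, ys, zs = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = grid.astype(float)

    dmin = np.full(len(centers), np.inf)
    if len(pts) == 1:
        dmin = np.linalg.norm(centers - pts[0], axis=1)
    else:
        for a, b in zip(pts[:-1], pts[1:]):
            dmin = np.minimum(dmin, _segment_distances(centers, a, b))
    hit = grid[dmin <= r + 1e-12]
    return {xyz_to_id(x, y, z, (nx, ny, nz)) for x, y, z in hit}


@dataclass
class AnnotationSet:
    """The tagged-voxel store.

    Keeps a replayable event log of add/erase operations; the *live* state
    (at most one label per voxel, latest iteration wins) is what training
    consumes.
    """

    dims: tuple[int, int, int]
    volume_name: str = ""
    _events: list[_Event] = field(default_factory=list)
    _live: dict[int, VoxelTag] = field(default_factory=dict)

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or min(self.dims) < 1:
            raise ValidationError("dims must be three positive integers")

    # -- queries -----------------------------------------------------------
    @property
    def max_iteration(self) -> int:
        return max((e.iteration for e in self._events), default=0)

    def live_tags(self) -> list[VoxelTag]:
        """Live tags sorted by voxel_id."""
        return [self._live[v] for v in sorted(self._live)]

    def label_counts(self) -> dict[str, int]:
        counts = {POSITIVE: 0, NEGATIVE: 0}
        for t in self._live.values():
            counts[t.label] += 1
        return counts

    def __len__(self) -> int:
        return len(self._live)

    # -- mutations ---------------------------------------------------------
    def add_tags(self, voxel_ids: Iterable[int], label: str, iteration: int) -> "AnnotationSet":
        """Tag voxels with ``label`` at ``iteration``; a voxel re-tagged at a
        later (or equal, same-label) iteration takes the newest label."""
        if label not in _LABELS:
            raise ValidationError(f"label must be one of {_LABELS}")
        iteration = int(iteration)
        if iteration < 1:
            raise ValidationError("iteration must be >= 1")
        if iteration < self.max_iteration:
            raise ValidationError(
                f"iteration {iteration} precedes existing max {self.max_iteration}"
            )
        ids = _check_ids(voxel_ids, self.dims)
        # same-iteration conflicting labels are a contradiction in supervision
        for v in ids:
            tag = self._live.get(v)
            if tag is not None and tag.iteration == iteration and tag.label != label:
                raise ValidationError(
                    f"voxel {v} tagged with both labels in iteration {iteration}"
                )
        self._events.append(_Event("add", tuple(ids), label, iteration))
        for v in ids:
            self._live[v] = VoxelTag(v, label, iteration)
        return self

    def erase_tags(self, voxel_ids: Iterable[int]) -> "AnnotationSet":
        """Remove the live label of the named voxels (no-op when untagged);
        the erase event stays in the history."""
        ids = _check_ids(voxel_ids, self.dims)
        self._events.append(_Event("erase", tuple(ids), None, self.max_iteration))
        for v in ids:
            self._live.pop(v, None)
        return self

    def add_stroke(self, stroke: Stroke, iteration: int) -> "AnnotationSet":
        return self.add_tags(stroke_to_voxels(stroke, self.dims), stroke.label, iteration)


def training_table(ann: AnnotationSet, features: "FeatureMatrix"):
    """Assemble the supervised table: feature rows for every live-tagged
    voxel (sorted by voxel_id) and binary labels (positive -> 1).

    Raises :class:`SchemaError` when a tagged voxel has no feature row.
    """
    tags = ann.live_tags()
    row_of = {v: i for i, v in enumerate(features.voxel_ids)}
    rows, y = [], []
    for t in tags:
        if t.voxel_id not in row_of:
            raise SchemaError(f"no feature row for tagged voxel {t.voxel_id}")
        rows.append(row_of[t.voxel_id])
        y.append(1 if t.label == POSITIVE else 0)
    X = features.values[rows] if rows else features.values[:0]
    return X, np.asarray(y, dtype=np.int64)
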