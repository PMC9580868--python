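"""Synthetic phantoms and simulated annotation strokes.

Two phantom families emulate the structures the pipeline targets: bulky
high-intensity ellipsoidal blobs (tumour-like masses) and thin tubular
networks grown as momentum-driven random walks (neurite-like branches),
both embedded in a noisy background.  Ground truth is the noiseless
geometry; the intensity volume adds Gaussian or Poisson noise on top of a
two-level signal.  ``simulate_strokes`` stands in for a user sweeping a
VR controller: short labelled polylines drawn inside the object (positive)
or through the background (negative), guaranteed label-consistent with the
ground truth.

Defaults: object mean 200, background mean 10 (a high-contrast 8-bit-like
regime); noisy fixtures use Gaussian sigma at 20% of that contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .annotation import AnnotationSet, Stroke, stroke_to_voxels, xyz_to_id
from .errors import ValidationError
from .volume_io import VolumeStack

DEFAULT_OBJECT_MEAN = 200.0
DEFAULT_BACKGROUND_MEAN = 10.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one reproducible phantom.

    ``geometry`` holds kind-specific parameters — blobs: ``ellipsoids``, a
    list of (center, radii) pairs; tubes: ``n_tubes``, ``tube_radius``,
    ``n_steps``.
    """

    kind: str  # "blob" | "tubes"
    dims: tuple[int, int, int] = (32, 32, 32)
    object_mean: float = DEFAULT_OBJECT_MEAN
    background_mean: float = DEFAULT_BACKGROUND_MEAN
    noise: str = "gaussian"  # "gaussian" | "poisson"
    noise_sigma: float = 0.0  # for gaussian noise, in intensity units
    geometry: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("blob", "tubes"):
            raise ValidationError(f"phantom kind must be blob or tubes, got {self.kind!r}")
        if min(self.dims) < 16:
            raise ValidationError("phantom dims must be >= 16 per axis")
        if self.object_mean < 0 or self.background_mean < 0:
            raise ValidationError("intensity means must be >= 0")
        if self.noise not in ("gaussian", "poisson"):
            raise ValidationError("noise model must be gaussian or poisson")


def _blob_gt(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.dims
    # default half-axes sit between lattice planes so the voxelized surface
    # has no degenerate single-voxel tips at the axis extremes
    ellipsoids = spec.geometry.get(
        "ellipsoids",
        [((nx / 2, ny / 2, nz / 2), (0.26 * nx, 0.225 * ny, 0.19 * nz))],
    )
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    gt = np.zeros((nz, ny, nx), dtype=bool)
    for center, radii in ellipsoids:
        cx, cy, cz = center
        rx, ry, rz = radii
        if 2 * max(rx, ry, rz) > max(nx, ny, nz):
            raise ValidationError("ellipsoid larger than the volume")
        gt |= (
            ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2
        ) <= 1.0
    return gt


def _tubes_gt(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    nx, ny, nz = spec.dims
    n_tubes = int(spec.geometry.get("n_tubes", 3))
    radius = float(spec.geometry.get("tube_radius", 1.5))
    n_steps = int(spec.geometry.get("n_steps", 120))
    persistence = float(spec.geometry.get("persistence", 0.9))
    if 2 * radius > max(nx, ny, nz):
        raise ValidationError("tube radius larger than the volume")

    path = np.zeros((nz, ny, nx), dtype=bool)
    lo = np.array([1.0, 1.0, 1.0])
    hi = np.array([nx - 2, ny - 2, nz - 2], dtype=float)
    for _ in range(n_tubes):
        pos = rng.uniform(low=lo + 2, high=hi - 2)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for _ in range(n_steps):
            # momentum walk: mostly straight, gently meandering
            direction = persistence * direction + (1 - persistence) * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = np.clip(pos + direction, lo, hi)
            x, y, z = np.round(pos).astype(int)
            path[z, y, x] = True
    dist = ndimage.distance_transform_edt(~path)
    return dist <= radius


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeStack, np.ndarray]:
    """Build (volume, ground truth) from a phantom recipe.

    The same spec (seed included) always yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "blob":
        gt = _blob_gt(spec)
    else:
        gt = _tubes_gt(spec, rng)

    signal = np.where(gt, spec.object_mean, spec.background_mean).astype(np.float64)
    if spec.noise == "gaussian":
        if spec.noise_sigma > 0:
            signal = signal + rng.normal(0.0, spec.noise_sigma, size=signal.shape)
    else:
        signal = rng.poisson(np.maximum(signal, 0.0)).astype(np.float64)
    vol = VolumeStack(data=signal, name=f"{spec.kind}_seed{spec.seed}")
    return vol, gt


def _random_polyline_in(
    region: np.ndarray, dims, rng: np.random.Generator, length: int = 5
) -> list[tuple[float, float, float]]:
    """A short polyline hopping between nearby voxels of ``region``."""
    zs, ys, xs = np.nonzero(region)
    if len(zs) == 0:
        raise ValidationError("region is empty")
    i = rng.integers(len(zs))
    pts = [(float(xs[i]), float(ys[i]), float(zs[i]))]
    coords = np.column_stack([xs, ys, zs]).astype(float)
    for _ in range(length - 1):
        last = np.array(pts[-1])
        d = np.linalg.norm(coords - last, axis=1)
        near = np.nonzero((d > 0) & (d <= 4.0))[0]
        if len(near) == 0:
            break
        j = near[rng.integers(len(near))]
        pts.append(tuple(coords[j]))
    return pts


def simulate_strokes(
    gt: np.ndarray,
    dims: tuple[int, int, int] | None = None,
    n_pos_strokes: int = 2,
    n_neg_strokes: int = 2,
    radius: float = 1.0,
    seed: int = 0,
) -> AnnotationSet:
    """Emulate a user's tagging session on a known ground truth.

    Positive strokes follow the object, negative strokes streak through the
    background; swept voxels are intersected with the matching class so
    every returned tag is label-consistent with ``gt``.
    """
    gt = np.asarray(gt).astype(bool)
    if dims is None:
        nz, ny, nx = gt.shape
        dims = (nx, ny, nz)
    if not gt.any() or gt.all():
        raise ValidationError("ground truth must contain both classes")
    rng = np.random.default_rng(seed)
    ann = AnnotationSet(dims=dims)

    flat_gt = gt.reshape(-1)  # voxel-ID order (x fastest)

    def add(polyline_fn, label: str, want_positive_class: bool, n: int):
        added = 0
        attempts = 0
        while added < n and attempts < 20 * n:
            attempts += 1
            pts = polyline_fn()
            stroke = Stroke(polyline=tuple(pts), radius=radius, label=label)
            swept = stroke_to_voxels(stroke, dims)
            keep = {v for v in swept if flat_gt[v] == want_positive_class}
            if keep:
                ann.add_tags(keep, label, iteration=1)
                added += 1
        if added < n:
            raise ValidationError(f"could not place {n} {label} strokes")

    nx, ny, nz = dims
    zs, ys, xs = np.nonzero(gt)
    centroid = np.array([xs.mean(), ys.mean(), zs.mean()])

    def positive_polyline():
        # short wiggle following the object
        return _random_polyline_in(gt, dims, rng)

    def negative_polyline():
        # a large streak swept across the scene, aimed loosely at the
        # object so near-boundary background gets sampled too
        a = rng.uniform(low=(0, 0, 0), high=(nx - 1, ny - 1, nz - 1))
        through = centroid + rng.normal(scale=max(nx, ny, nz) / 6.0, size=3)
        b = np.clip(2.0 * through - a, 0, np.array([nx, ny, nz]) - 1)
        return [tuple(a), tuple(through), tuple(b)]

    add(positive_polyline, "positive", True, n_pos_strokes)
    add(negative_polyline, "negative", False, n_neg_strokes)
    return ann


def standard_fixtures() -> dict[str, tuple[PhantomSpec, VolumeStack, np.ndarray]]:
    """The frozen phantom suite used throughout the tests.

    - ``blob_clean``: 32^3, one ellipsoid, no noise.
    - ``blob_noisy``: 32^3, one ellipsoid, Gaussian sigma = 20% of contrast.
    - ``tubes_noisy``: 48^3, 3 tubes of radius 1.5, same relative noise.
    """
    contrast = DEFAULT_OBJECT_MEAN - DEFAULT_BACKGROUND_MEAN
    specs = {
        "blob_clean": PhantomSpec(
            kind="blob", dims=(32, 32, 32), noise_sigma=0.0, seed=11
        ),
        "blob_noisy": PhantomSpec(
            kind="blob", dims=(32, 32, 32), noise_sigma=0.2 * contrast, seed=12
        ),
        "tubes_noisy": PhantomSpec(
            kind="tubes",
            dims=(48, 48, 48),
            noise_sigma=0.2 * contrast,
            geometry={"n_tubes": 3, "tube_radius": 1.5},
            seed=13,
        ),
    }
    out = {}
    for name, spec in specs.items():
        vol, gt = generate_phantom(spec)
        out[name] = (spec, vol, gt)
    return out
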