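"""The multi-scale 3D feature bank.

Each voxel is described by a fixed, ordered vector of spatial-filter
responses evaluated on an isotropic cubic neighbourhood.  The default bank
has 56 features: the raw intensity (``PIXEL_VALUE``) plus 11 filter kinds,
each at the five odd kernel sizes {3, 5, 7, 9, 11}:

=====================  =======================================================
kind                   response at a voxel
=====================  =======================================================
gaussian               truncated, normalised Gaussian smoothing (sigma = k/6)
mean / median          box average / median over the k^3 window
minimum / maximum      order statistics over the window
range                  maximum - minimum
stddev                 population standard deviation over the window
gradient_magnitude     |grad| from Gaussian-derivative kernels
laplacian_of_gaussian  trace of the Gaussian Hessian (zero-sum kernel)
difference_of_gaussians G(sigma) - G(2*sigma), both truncated to the window
hessian_max_eigen      largest eigenvalue of the Gaussian Hessian
=====================  =======================================================

All Gaussian-family kernels are sampled and truncated to the stated kernel
size (so a k^3 neighbourhood fully determines the response) and smoothing
kernels are renormalised to unit sum; derivative kernels are exactly
zero-sum, so every non-smoothing feature vanishes on a constant field.
Borders use mirror padding.  Features are computed in 64-bit reals on
intensities cast to real; no normalisation is applied (tree learners are
scale-free and ``PIXEL_VALUE`` stays in native units).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import ndimage

from .annotation import id_to_xyz
from .errors import ValidationError
from .volume_io import VolumeStack

KERNEL_SIZES = (3, 5, 7, 9, 11)
FILTER_KINDS = (
    "gaussian",
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "stddev",
    "gradient_magnitude",
    "laplacian_of_gaussian",
    "difference_of_gaussians",
    "hessian_max_eigen",
)
PIXEL_VALUE = "pixel_value"


@dataclass(frozen=True)
class FeatureDescriptor:
    filter_kind: str
    kernel_size: int | None = None  # None only for pixel_value

    def __post_init__(self):
        if self.filter_kind == PIXEL_VALUE:
            if self.kernel_size is not None:
                raise ValidationError("pixel_value takes no kernel size")
        else:
            if self.filter_kind not in FILTER_KINDS:
                raise ValidationError(f"unknown filter kind {self.filter_kind!r}")
            if self.kernel_size not in KERNEL_SIZES:
                raise ValidationError(
                    f"kernel size must be one of {KERNEL_SIZES}, got {self.kernel_size}"
                )

    @property
    def name(self) -> str:
        if self.filter_kind == PIXEL_VALUE:
            return "PIXEL_VALUE"
        return f"{self.filter_kind.upper()}_k{self.kernel_size}"


@dataclass(frozen=True)
class FeatureBankSpec:
    descriptors: tuple[FeatureDescriptor, ...]

    def __post_init__(self):
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValidationError("descriptor names must be unique within a bank")

    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def max_kernel_size(self) -> int:
        return max((d.kernel_size for d in self.descriptors if d.kernel_size), default=1)

    @property
    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.names).encode()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(
            [{"kind": d.filter_kind, "kernel_size": d.kernel_size} for d in self.descriptors]
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureBankSpec":
        items = json.loads(text)
        return cls(tuple(FeatureDescriptor(i["kind"], i["kernel_size"]) for i in items))


@dataclass
class FeatureMatrix:
    voxel_ids: list[int]
    values: np.ndarray  # (n_voxels, n_features) float64
    spec_hash: str
    feature_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.voxel_ids):
            raise ValidationError("row count must equal number of voxel ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")


def default_bank() -> FeatureBankSpec:
    """The canonical 56-feature bank: PIXEL_VALUE + 11 kinds x 5 sizes."""
    descs = [FeatureDescriptor(PIXEL_VALUE)]
    for kind in FILTER_KINDS:
        for k in KERNEL_SIZES:
            descs.append(FeatureDescriptor(kind, k))
    return FeatureBankSpec(tuple(descs))


# ---------------------------------------------------------------------------
# kernels (all truncated to the stated kernel size; sigma = k/6)

@lru_cache(maxsize=None)
def _gauss1d(k: int, sigma_scale: float = 1.0) -> np.ndarray:
    r = k // 2
    sigma = (k / 6.0) * sigma_scale
    i = np.arange(-r, r + 1, dtype=np.float64)
    w = np.exp(-(i**2) / (2.0 * sigma**2))
    return w / w.sum()


@lru_cache(maxsize=None)
def _dgauss1d(k: int) -> np.ndarray:
    """First derivative of the normalised, truncated Gaussian (zero-sum)."""
    r = k // 2
    sigma = k / 6.0
    i = np.arange(-r, r + 1, dtype=np.float64)
    return -(i / sigma**2) * _gauss1d(k)


@lru_cache(maxsize=None)
def _ddgauss1d(k: int) -> np.ndarray:
    """Second derivative of the truncated Gaussian, recentred to zero sum."""
    r = k // 2
    sigma = k / 6.0
    i = np.arange(-r, r + 1, dtype=np.float64)
    h = ((i**2 - sigma**2) / sigma**4) * _gauss1d(k)
    return h - h.mean()


def _outer3(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return a[:, None, None] * b[None, :, None] * c[None, None, :]


@lru_cache(maxsize=None)
def _kernel3d(kind: str, k: int) -> np.ndarray | tuple[np.ndarray, ...]:
    """Dense 3D kernel(s) for the Gaussian-family filters, axis order (z, y, x)."""
    g = _gauss1d(k)
    d = _dgauss1d(k)
    h = _ddgauss1d(k)
    if kind == "gaussian":
        return _outer3(g, g, g)
    if kind == "difference_of_gaussians":
        g2 = _gauss1d(k, sigma_scale=2.0)
        return _outer3(g, g, g) - _outer3(g2, g2, g2)
    if kind == "laplacian_of_gaussian":
        return _outer3(h, g, g) + _outer3(g, h, g) + _outer3(g, g, h)
    if kind == "gradient_components":
        return (_outer3(d, g, g), _outer3(g, d, g), _outer3(g, g, d))
    if kind == "hessian_components":
        # order: (zz, yy, xx, zy, zx, yx)
        return (
            _outer3(h, g, g),
            _outer3(g, h, g),
            _outer3(g, g, h),
            _outer3(d, d, g),
            _outer3(d, g, d),
            _outer3(g, d, d),
        )
    raise ValidationError(f"no dense kernel for kind {kind!r}")


def _hessian_max_eig(components: Sequence[np.ndarray]) -> np.ndarray:
    """Largest eigenvalue of the symmetric 3x3 Hessian at every voxel."""
    zz, yy, xx, zy, zx, yx = components
    H = np.empty(zz.shape + (3, 3), dtype=np.float64)
    H[..., 0, 0] = zz
    H[..., 1, 1] = yy
    H[..., 2, 2] = xx
    H[..., 0, 1] = H[..., 1, 0] = zy
    H[..., 0, 2] = H[..., 2, 0] = zx
    H[..., 1, 2] = H[..., 2, 1] = yx
    return np.linalg.eigvalsh(H)[..., -1]


# ---------------------------------------------------------------------------
# dense path (scipy.ndimage, mirror borders)

_MODE = "reflect"  # scipy 'reflect' == np.pad 'symmetric' (mirror about the edge)


def _dense_response(data: np.ndarray, desc: FeatureDescriptor) -> np.ndarray:
    kind, k = desc.filter_kind, desc.kernel_size
    if kind == PIXEL_VALUE:
        return data.copy()
    if kind == "mean":
        box = np.full((k, k, k), 1.0 / k**3)
        return ndimage.correlate(data, box, mode=_MODE)
    if kind == "median":
        return ndimage.median_filter(data, size=k, mode=_MODE)
    if kind == "minimum":
        return ndimage.minimum_filter(data, size=k, mode=_MODE)
    if kind == "maximum":
        return ndimage.maximum_filter(data, size=k, mode=_MODE)
    if kind == "range":
        return ndimage.maximum_filter(data, size=k, mode=_MODE) - ndimage.minimum_filter(
            data, size=k, mode=_MODE
        )
    if kind == "stddev":
        box = np.full((k, k, k), 1.0 / k**3)
        m = ndimage.correlate(data, box, mode=_MODE)
        m2 = ndimage.correlate(data**2, box, mode=_MODE)
        return np.sqrt(np.clip(m2 - m**2, 0.0, None))
    if kind in ("gaussian", "difference_of_gaussians", "laplacian_of_gaussian"):
        return ndimage.correlate(data, _kernel3d(kind, k), mode=_MODE)
    if kind == "gradient_magnitude":
        comps = [
            ndimage.correlate(data, ker, mode=_MODE)
            for ker in _kernel3d("gradient_components", k)
        ]
        return np.sqrt(sum(c**2 for c in comps))
    if kind == "hessian_max_eigen":
        comps = [
            ndimage.correlate(data, ker, mode=_MODE)
            for ker in _kernel3d("hessian_components", k)
        ]
        return _hessian_max_eig(comps)
    raise ValidationError(f"unknown filter kind {kind!r}")


def compute_features_full(
    vol: VolumeStack,
    spec: FeatureBankSpec | None = None,
    block_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Dense feature volumes, shape ``(n_features, nz, ny, nx)``.

    When ``block_shape`` is given the volume is processed tile by tile with
    a mirror-padded halo of the maximum kernel radius; the result is
    identical to the monolithic computation.
    """
    spec = spec or default_bank()
    data = vol.data.astype(np.float64)
    halo = spec.max_kernel_size // 2
    nz, ny, nx = data.shape
    out = np.empty((len(spec),) + data.shape, dtype=np.float64)

    if block_shape is None:
        for i, desc in enumerate(spec.descriptors):
            out[i] = _dense_response(data, desc)
        return out

    bz, by, bx = (int(b) for b in block_shape)
    if min(bz, by, bx) < halo:
        raise ValidationError(
            f"block shape {block_shape} smaller than the kernel halo {halo}"
        )
    padded = np.pad(data, halo, mode="symmetric")
    for z0 in range(0, nz, bz):
        for y0 in range(0, ny, by):
            for x0 in range(0, nx, bx):
                z1, y1, x1 = min(z0 + bz, nz), min(y0 + by, ny), min(x0 + bx, nx)
                tile = padded[z0 : z1 + 2 * halo, y0 : y1 + 2 * halo, x0 : x1 + 2 * halo]
                for i, desc in enumerate(spec.descriptors):
                    resp = _dense_response(tile, desc)
                    out[i, z0:z1, y0:y1, x0:x1] = resp[
                        halo : halo + (z1 - z0),
                        halo : halo + (y1 - y0),
                        halo : halo + (x1 - x0),
                    ]
    return out


# ---------------------------------------------------------------------------
# sparse path: direct neighbourhood evaluation at individual voxels

def _patch_response(patch: np.ndarray, desc: FeatureDescriptor) -> float:
    kind, k = desc.filter_kind, desc.kernel_size
    if kind == PIXEL_VALUE:
        c = patch.shape[0] // 2
        return float(patch[c, c, c])
    if kind == "mean":
        return float(patch.mean())
    if kind == "median":
        return float(np.median(patch))
    if kind == "minimum":
        return float(patch.min())
    if kind == "maximum":
        return float(patch.max())
    if kind == "range":
        return float(patch.max() - patch.min())
    if kind == "stddev":
        m = patch.mean()
        return float(np.sqrt(max((patch**2).mean() - m**2, 0.0)))
    if kind in ("gaussian", "difference_of_gaussians", "laplacian_of_gaussian"):
        return float((_kernel3d(kind, k) * patch).sum())
    if kind == "gradient_magnitude":
        comps = [(ker * patch).sum() for ker in _kernel3d("gradient_components", k)]
        return float(np.sqrt(sum(c**2 for c in comps)))
    if kind == "hessian_max_eigen":
        zz, yy, xx, zy, zx, yx = (
            float((ker * patch).sum()) for ker in _kernel3d("hessian_components", k)
        )
        H = np.array([[zz, zy, zx], [zy, yy, yx], [zx, yx, xx]])
        return float(np.linalg.eigvalsh(H)[-1])
    raise ValidationError(f"unknown filter kind {kind!r}")


def compute_features_at(
    vol: VolumeStack,
    voxel_ids: Sequence[int],
    spec: FeatureBankSpec | None = None,
) -> FeatureMatrix:
    """Feature rows centred at the given voxels, by direct neighbourhood
    evaluation on mirror-padded patches.  Row order follows ``voxel_ids``.
    """
    spec = spec or default_bank()
    data = vol.data.astype(np.float64)
    dims = vol.dims
    n_total = data.size
    ids = [int(v) for v in voxel_ids]
    for v in ids:
        if not 0 <= v < n_total:
            raise ValidationError(f"voxel id {v} out of bounds for dims {dims}")
    halo = spec.max_kernel_size // 2
    padded = np.pad(data, halo, mode="symmetric")
    values = np.empty((len(ids), len(spec)), dtype=np.float64)
    for row, vid in enumerate(ids):
        x, y, z = id_to_xyz(vid, dims)
        # padded centre sits at (z+halo, y+halo, x+halo)
        big = padded[z : z + 2 * halo + 1, y : y + 2 * halo + 1, x : x + 2 * halo + 1]
        for j, desc in enumerate(spec.descriptors):
            if desc.filter_kind == PIXEL_VALUE:
                values[row, j] = data[z, y, x]
                continue
            r = desc.kernel_size // 2
            c = halo
            patch = big[c - r : c + r + 1, c - r : c + r + 1, c - r : c + r + 1]
            values[row, j] = _patch_response(patch, desc)
    return FeatureMatrix(
        voxel_ids=ids, values=values, spec_hash=spec.hash, feature_names=spec.names
    )


def features_as_matrix(dense: np.ndarray, spec: FeatureBankSpec) -> np.ndarray:
    """Flatten dense feature volumes to an (n_voxels, n_features) design
    matrix in voxel-ID order (x fastest)."""
    n_feat = dense.shape[0]
    # dense axes are (feature, z, y, x); voxel-ID order is x, then y, then z
    return dense.reshape(n_feat, -1).T
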