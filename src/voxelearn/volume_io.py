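"""Volume, transfer-function and annotation I/O.

Volumes are multi-page TIFF stacks (one page per z slice) or NIfTI-1 files.
In memory a :class:`VolumeStack` stores its grid as a ``(nz, ny, nx)`` array
so that element ``[0, 0, 0]`` is the first pixel of the first slice of the
file; the public ``dims`` are ``(nx, ny, nz)`` to match the voxel-ID
linearisation ``id = x + nx*(y + ny*z)``.

Transfer functions map normalised intensity in [0, 1] to colour and opacity
with monotone piecewise-linear interpolation and round-trip through a small
JSON dialect, as do annotation sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import tifffile

from .annotation import AnnotationSet, _LABELS
from .errors import FormatError, ValidationError


@dataclass
class VolumeStack:
    """A 3D scalar intensity grid.

    ``data`` is indexed ``[z, y, x]``; ``dims`` reports ``(nx, ny, nz)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # a single slice is a 1-deep stack
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValidationError("all dims must be >= 1")
        if not np.all(np.isfinite(np.asarray(self.data, dtype=np.float64))):
            raise ValidationError("intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or min(self.spacing) <= 0:
            raise ValidationError("spacing must be three strictly positive values")

    @property
    def dims(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    def intensity_range(self) -> tuple[float, float]:
        return float(self.data.min()), float(self.data.max())

    def normalized(self) -> np.ndarray:
        """Intensities rescaled to [0, 1] by the volume's (min, max);
        a constant volume maps to 0."""
        lo, hi = self.intensity_range()
        arr = self.data.astype(np.float64)
        if hi == lo:
            return np.zeros_like(arr)
        return (arr - lo) / (hi - lo)


@dataclass
class TransferFunction:
    """Piecewise-linear map from normalised intensity to (R, G, B, alpha).

    Control points are ``(x, opacity, (r, g, b))`` with strictly increasing
    ``x``, the first at 0 and the last at 1.
    """

    points: list[tuple[float, float, tuple[float, float, float]]] = field(default_factory=list)

    def __post_init__(self):
        pts = [(float(x), float(op), tuple(float(c) for c in rgb)) for x, op, rgb in self.points]
        if len(pts) < 2:
            raise ValidationError("transfer function needs >= 2 control points")
        xs = [p[0] for p in pts]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValidationError("control-point intensities must be strictly increasing")
        if xs[0] != 0.0 or xs[-1] != 1.0:
            raise ValidationError("control points must start at 0 and end at 1")
        for x, op, rgb in pts:
            if not (0.0 <= op <= 1.0) or any(not (0.0 <= c <= 1.0) for c in rgb):
                raise ValidationError("opacity and colour channels must lie in [0, 1]")
        self.points = pts

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        """RGBA at each normalised intensity; output shape = input + (4,)."""
        v = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
        xs = np.array([p[0] for p in self.points])
        ops = np.array([p[1] for p in self.points])
        rgbs = np.array([p[2] for p in self.points])
        out = np.empty(v.shape + (4,), dtype=np.float64)
        for c in range(3):
            out[..., c] = np.interp(v, xs, rgbs[:, c])
        out[..., 3] = np.interp(v, xs, ops)
        return out


# ---------------------------------------------------------------------------
# volumes

_TIFF_SUFFIXES = {".tif", ".tiff"}
_NIFTI_SUFFIXES = {".nii"}


def _sniff_format(path: Path, format: str) -> str:
    if format not in ("auto", "tiff", "nifti"):
        raise FormatError(f"unsupported format tag {format!r}")
    if format != "auto":
        return format
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return "tiff"
    raise FormatError(f"cannot infer volume format from {path.name!r}")


def read_volume(path, format: str = "auto", channel: int | None = None) -> VolumeStack:
    """Read a TIFF stack or NIfTI volume into a :class:`VolumeStack`.

    A 4D file (channel axis) requires ``channel`` to pick one channel;
    otherwise a :class:`FormatError` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _sniff_format(path, format)
    try:
        if fmt == "tiff":
            data = tifffile.imread(str(path))
        else:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
            # NIfTI is x-fastest (x, y, z[, c]); bring to (z, y, x)
            data = np.transpose(data, tuple(reversed(range(data.ndim))))
    except Exception as exc:  # noqa: BLE001 - reported as a format error
        raise FormatError(f"could not read {path} as {fmt}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 4:
        # channel-first after the transposes above: (c, z, y, x)
        if data.shape[0] == 1:
            data = data[0]
        elif channel is None:
            raise FormatError(
                f"{path.name} has {data.shape[0]} channels; pass channel= to select one"
            )
        else:
            if not 0 <= channel < data.shape[0]:
                raise FormatError(f"channel {channel} out of range for {path.name}")
            data = data[channel]
    if data.ndim not in (2, 3):
        raise FormatError(f"{path.name} is not a 3D volume (shape {data.shape})")
    return VolumeStack(data=data, name=path.stem)


def write_volume(vol, path, format: str = "auto") -> None:
    """Write a :class:`VolumeStack` or probability map to TIFF/NIfTI.

    Probability maps (real-valued grids) are stored as 32-bit floats.
    """
    from .inference import ProbabilityMap  # local import to avoid a cycle

    path = Path(path)
    fmt = _sniff_format(path, format)
    if isinstance(vol, ProbabilityMap):
        data = vol.data.astype(np.float32)
    else:
        data = vol.data
        if np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
    try:
        if fmt == "tiff":
            # one grayscale page per z slice (never RGB-guessing small dims)
            tifffile.imwrite(str(path), data, photometric="minisblack")
        else:
            img = nib.Nifti1Image(
                np.transpose(data, (2, 1, 0)), affine=np.eye(4)
            )
            nib.save(img, str(path))
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"could not write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# transfer functions

def save_transfer_function(tf: TransferFunction, path) -> None:
    doc = {
        "points": [
            {"x": x, "opacity": op, "rgb": list(rgb)} for x, op, rgb in tf.points
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_transfer_function(path) -> TransferFunction:
    try:
        doc = json.loads(Path(path).read_text())
        pts = [(p["x"], p["opacity"], tuple(p["rgb"])) for p in doc["points"]]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValidationError(f"malformed transfer-function JSON in {path}: {exc}") from exc
    return TransferFunction(points=pts)


# ---------------------------------------------------------------------------
# annotations

def save_annotations(ann: AnnotationSet, path) -> None:
    """Serialise the live tags of an annotation set.

    Dialect: ``{"volume": "<name>", "dims": [nx, ny, nz],
    "tags": [{"id": 432, "label": "positive", "iteration": 1}, ...]}``.
    """
    doc = {
        "volume": ann.volume_name,
        "dims": list(ann.dims),
        "tags": [
            {"id": t.voxel_id, "label": t.label, "iteration": t.iteration}
            for t in ann.live_tags()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_annotations(path) -> AnnotationSet:
    try:
        doc = json.loads(Path(path).read_text())
        dims = tuple(int(d) for d in doc["dims"])
        tags = doc["tags"]
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed annotation JSON in {path}: {exc}") from exc
    ann = AnnotationSet(dims=dims, volume_name=doc.get("volume", ""))
    seen: dict[int, str] = {}
    for t in tags:
        label = t.get("label")
        if label not in _LABELS:
            raise ValidationError(f"unknown label {label!r} in {path}")
        vid = int(t["id"])
        if vid in seen and seen[vid] != label:
            raise ValidationError(f"voxel {vid} carries conflicting labels in {path}")
        seen[vid] = label
    # replay in iteration order to reconstruct the live state
    for t in sorted(tags, key=lambda t: int(t.get("iteration", 1))):
        ann.add_tags([int(t["id"])], t["label"], int(t.get("iteration", 1)))
    return ann
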