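"""Scoring probability maps against reference segmentations.

Dice is computed on the prediction thresholded at a configurable cut
(default 0.5, ties counting as positive); RMSE compares the raw
probabilities against the binary reference over every voxel of the volume.
Both masks empty scores Dice 1 by convention.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .inference import ProbabilityMap, infer_volume
from .volume_io import VolumeStack


def _as_array(obj) -> np.ndarray:
    if isinstance(obj, (ProbabilityMap, VolumeStack)):
        return np.asarray(obj.data)
    return np.asarray(obj)


def _binary_gt(gt) -> np.ndarray:
    arr = _as_array(gt)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError(f"ground truth must be binary, found values {uniq[:5]}")
    return arr.astype(bool)


def _check_dims(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValidationError(f"dims mismatch: {a.shape} vs {b.shape}")


@dataclass
class EvaluationReport:
    dice: float
    rmse: float
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    wall_times: dict = field(default_factory=dict)  # informational only

    def counts_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "rmse": self.rmse,
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "wall_times": self.wall_times,
        }


def dice(pred, gt, threshold: float = 0.5) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of the thresholded prediction.

    A voxel with probability exactly equal to ``threshold`` counts as
    positive.  Returns 1.0 when both masks are empty.
    """
    p = _as_array(pred)
    g = _binary_gt(gt)
    _check_dims(p, g)
    if p.dtype == bool:
        mask = p
    else:
        mask = p >= threshold
    inter = int(np.logical_and(mask, g).sum())
    denom = int(mask.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom


def rmse(pred, gt) -> float:
    """Root mean squared error between probabilities and the binary
    reference, over all voxels."""
    p = _as_array(pred).astype(np.float64)
    g = _binary_gt(gt).astype(np.float64)
    _check_dims(p, g)
    return float(np.sqrt(np.mean((p - g) ** 2)))


def evaluate_run(
    model,
    vol: VolumeStack,
    gt,
    spec=None,
    threshold: float = 0.5,
    block_shape=None,
) -> EvaluationReport:
    """Infer the full volume and score it against ``gt``.

    Stage wall-times are recorded for information only.
    """
    g = _binary_gt(gt)
    if g.shape != vol.data.shape:
        raise ValidationError(f"gt dims {g.shape} do not match volume {vol.data.shape}")
    t0 = time.perf_counter()
    pm = infer_volume(model, vol, spec, block_shape=block_shape)
    t1 = time.perf_counter()
    mask = pm.data >= threshold
    tp = int(np.logical_and(mask, g).sum())
    fp = int(np.logical_and(mask, ~g).sum())
    fn = int(np.logical_and(~mask, g).sum())
    tn = int(np.logical_and(~mask, ~g).sum())
    d = dice(pm, g, threshold=threshold)
    r = rmse(pm, g)
    t2 = time.perf_counter()
    return EvaluationReport(
        dice=d,
        rmse=r,
        threshold=threshold,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        wall_times={"inference_s": t1 - t0, "scoring_s": t2 - t1},
    )
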