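"""Dense inference and overlay compositing.

``infer_volume`` evaluates the feature bank over the whole volume (tiled
with a mirror-padded halo when asked) and applies a trained model voxel by
voxel, yielding a :class:`ProbabilityMap`.  ``overlay`` fuses up to four
channels — raw volumes and/or probability maps, each with its own transfer
function — back to front with the "over" alpha operator; the default
probability transfer function maps 0 to blue and 1 to red.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationSet, training_table
from .errors import SchemaError, ValidationError
from .feature_bank import (
    FeatureBankSpec,
    compute_features_at,
    compute_features_full,
    features_as_matrix,
)
from .learners import StrongLearnerModel, TrainedModel, train_classifier, train_strong
from .volume_io import TransferFunction, VolumeStack

LOG_EPS = 1e-12


@dataclass
class ProbabilityMap:
    """Per-voxel probability of the positive class, dims = source dims."""

    data: np.ndarray  # (nz, ny, nx) float in [0, 1]
    model_fingerprint: str = ""
    class_label: str = "positive"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError("probability map must be 3D")
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValidationError("probabilities must lie in [0, 1]")

    @property
    def dims(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)


@dataclass
class OverlayVolume:
    """Fused RGBA rendering, each channel in [0, 1]."""

    rgba: np.ndarray  # (nz, ny, nx, 4)

    def __post_init__(self):
        self.rgba = np.asarray(self.rgba, dtype=np.float64)
        if self.rgba.ndim != 4 or self.rgba.shape[-1] != 4:
            raise ValidationError("overlay must be (nz, ny, nx, 4)")
        if self.rgba.min() < -1e-12 or self.rgba.max() > 1 + 1e-12:
            raise ValidationError("RGBA channels must lie in [0, 1]")
        self.rgba = np.clip(self.rgba, 0.0, 1.0)


def infer_volume(
    model: TrainedModel | StrongLearnerModel,
    vol: VolumeStack,
    spec: FeatureBankSpec | None = None,
    block_shape: tuple[int, int, int] | None = None,
) -> ProbabilityMap:
    """Classify every voxel of ``vol`` with ``model``.

    Equivalent to ``predict_proba`` applied to the dense feature matrix;
    tiling through ``block_shape`` changes nothing beyond float round-off.
    """
    from .feature_bank import default_bank

    spec = spec or default_bank()
    if spec.hash != model.schema_hash:
        raise SchemaError("feature bank does not match the model's training schema")
    dense = compute_features_full(vol, spec, block_shape=block_shape)
    X = features_as_matrix(dense, spec)
    probs = np.empty(X.shape[0], dtype=np.float64)
    chunk = 65536
    for i in range(0, X.shape[0], chunk):
        probs[i : i + chunk] = model.predict_proba(X[i : i + chunk])
    nz, ny, nx = vol.data.shape
    return ProbabilityMap(
        data=probs.reshape(nz, ny, nx),
        model_fingerprint=model.schema_hash,
    )


def log_transform(pm: ProbabilityMap) -> np.ndarray:
    """Natural-log probabilities, floored at log(1e-12); monotone in p."""
    return np.log(np.maximum(pm.data, LOG_EPS))


def default_probability_tf() -> TransferFunction:
    """Probability colormap: 0 -> blue, 1 -> red, linear through magenta
    (no green); opacity ramps linearly so background stays transparent."""
    return TransferFunction(
        points=[
            (0.0, 0.0, (0.0, 0.0, 1.0)),
            (1.0, 1.0, (1.0, 0.0, 0.0)),
        ]
    )


def _channel_values(channel) -> np.ndarray:
    if isinstance(channel, ProbabilityMap):
        return channel.data  # already in [0, 1]
    if isinstance(channel, VolumeStack):
        return channel.normalized()
    raise ValidationError(f"cannot composite object of type {type(channel).__name__}")


def overlay(channels: list[tuple[object, TransferFunction]]) -> OverlayVolume:
    """Fuse 1-4 channels into an RGBA volume.

    Each channel's normalised values pass through its transfer function to
    per-voxel RGBA; channels are composited back to front (first channel at
    the back) with the "over" operator on straight alpha.
    """
    if not 1 <= len(channels) <= 4:
        raise ValidationError(f"overlay accepts 1-4 channels, got {len(channels)}")
    values = [_channel_values(ch) for ch, _ in channels]
    shapes = {v.shape for v in values}
    if len(shapes) != 1:
        raise ValidationError(f"channel dims mismatch: {sorted(shapes)}")

    out = np.zeros(values[0].shape + (4,), dtype=np.float64)
    for vals, (_, tf) in zip(values, channels):
        layer = tf.evaluate(vals)
        a_f = layer[..., 3:4]
        a_b = out[..., 3:4]
        a_out = a_f + a_b * (1.0 - a_f)
        rgb = layer[..., :3] * a_f + out[..., :3] * a_b * (1.0 - a_f)
        with np.errstate(invalid="ignore", divide="ignore"):
            rgb = np.where(a_out > 0, rgb / np.where(a_out > 0, a_out, 1.0), 0.0)
        out = np.concatenate([rgb, a_out], axis=-1)
    return OverlayVolume(rgba=out)


def grayscale_tf() -> TransferFunction:
    """Identity transfer function: R=G=B=alpha=normalised intensity."""
    return TransferFunction(
        points=[(0.0, 0.0, (0.0, 0.0, 0.0)), (1.0, 1.0, (1.0, 1.0, 1.0))]
    )


def iterate(
    model_spec,
    ann: AnnotationSet,
    vol: VolumeStack,
    spec: FeatureBankSpec | None = None,
    new_tags: list[tuple[set[int], str]] | None = None,
    seed: int = 0,
    iteration: int | None = None,
) -> TrainedModel | StrongLearnerModel:
    """One correction round: merge ``new_tags`` at iteration ``max + 1`` and
    retrain from scratch on the merged live tag set.

    ``new_tags`` is a list of ``(voxel_ids, label)`` pairs, all applied at
    the same new iteration; an empty list retrains on the unchanged tags.
    An explicit ``iteration`` must equal the previous maximum plus one.
    ``model_spec`` is a :class:`~voxelearn.learners.ClassifierSpec` or the
    string ``"strong"``.
    """
    from .feature_bank import default_bank

    spec = spec or default_bank()
    new_tags = new_tags or []
    if new_tags:
        it = ann.max_iteration + 1
        if iteration is not None and iteration != it:
            raise ValidationError(
                f"correction round must use iteration {it}, got {iteration}"
            )
        for voxel_ids, label in new_tags:
            ann.add_tags(voxel_ids, label, it)
    iteration = max(ann.max_iteration, 1)
    ids = [t.voxel_id for t in ann.live_tags()]
    feats = compute_features_at(vol, ids, spec)
    X, y = training_table(ann, feats)
    if model_spec == "strong":
        return train_strong(
            X, y, seed=seed, feature_names=spec.names, schema_hash=spec.hash,
            iteration=iteration,
        )
    return train_classifier(
        model_spec, X, y, feature_names=spec.names, schema_hash=spec.hash,
        iteration=iteration,
    )
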