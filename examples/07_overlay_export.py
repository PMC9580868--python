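"""Fuse raw data with the probability map for visual quality control.

The raw channel renders grayscale; the probability channel uses the
default transfer function (0 -> transparent blue, 1 -> opaque red) and is
composited on top with the "over" alpha operator.
"""

import tempfile
from pathlib import Path

import numpy as np
import tifffile

from voxelearn import (
    ClassifierSpec,
    compute_features_at,
    default_bank,
    infer_volume,
    simulate_strokes,
    standard_fixtures,
    train_classifier,
)
from voxelearn.annotation import training_table
from voxelearn.inference import default_probability_tf, grayscale_tf, overlay

bank = default_bank()
_, vol, gt = standard_fixtures()["blob_noisy"]
ann = simulate_strokes(gt, seed=0)
ids = [t.voxel_id for t in ann.live_tags()]
X, y = training_table(ann, compute_features_at(vol, ids, bank))
model = train_classifier(ClassifierSpec("RFC", seed=0), X, y,
                         feature_names=bank.names, schema_hash=bank.hash)
pm = infer_volume(model, vol, bank)

ov = overlay([(vol, grayscale_tf()), (pm, default_probability_tf())])
z = vol.dims[2] // 2
slice_rgba = ov.rgba[z]
print(f"overlay shape {ov.rgba.shape}; centre slice mean RGBA = "
      f"{np.round(slice_rgba.reshape(-1, 4).mean(axis=0), 3)}")

with tempfile.TemporaryDirectory() as td:
    out = Path(td) / "overlay.tif"
    tifffile.imwrite(out, ov.rgba.astype(np.float32), photometric="rgb",
                     extrasamples=["unassalpha"])
    print(f"wrote {out.name}: {out.stat().st_size / 1024:.0f} KiB RGBA stack")
# Inside the object the red channel dominates (p near 1); the background
# stays gray because the probability layer is transparent at p = 0.
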