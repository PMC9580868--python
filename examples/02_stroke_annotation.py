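"""Sweep labelled strokes through a volume and store the tagged voxels.

A stroke is a polyline with a brush radius; every voxel centre within the
radius receives the stroke's label.  Tags carry an iteration number so a
later correction round can overwrite earlier labels.
"""

import tempfile
from pathlib import Path

from voxelearn import (
    AnnotationSet,
    Stroke,
    load_annotations,
    save_annotations,
    stroke_to_voxels,
)

dims = (32, 32, 32)
ann = AnnotationSet(dims=dims, volume_name="demo")

pos = Stroke(polyline=((16, 16, 16), (20, 16, 16)), radius=1.5, label="positive")
neg = Stroke(polyline=((2, 2, 2), (28, 2, 2)), radius=1.0, label="negative")
ann.add_stroke(pos, iteration=1)
ann.add_stroke(neg, iteration=1)
print("after stroking:", ann.label_counts())

# a correction round: re-tag two of the positive voxels as negative
some = sorted(stroke_to_voxels(pos, dims))[:2]
ann.add_tags(some, "negative", iteration=2)
print("after correction:", ann.label_counts())

with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "annotations.json"
    save_annotations(ann, path)
    back = load_annotations(path)
    print(f"round-trip: {len(back)} live tags, max iteration {back.max_iteration}")
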