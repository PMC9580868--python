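"""The core loop: a handful of strokes trains a voxel classifier that
segments the whole volume.

Simulates a tagging session on the noisy blob phantom (2 positive + 2
negative strokes), trains a random forest on the 56-feature rows of the
tagged voxels, infers a dense probability map, and scores it.
"""

import numpy as np

from voxelearn import (
    ClassifierSpec,
    compute_features_at,
    default_bank,
    dice,
    infer_volume,
    rmse,
    simulate_strokes,
    standard_fixtures,
    train_classifier,
)
from voxelearn.annotation import training_table

bank = default_bank()
_, vol, gt = standard_fixtures()["blob_noisy"]

ann = simulate_strokes(gt, n_pos_strokes=2, n_neg_strokes=2, radius=1.0, seed=0)
print(f"tagging session: {len(ann)} voxels tagged ({ann.label_counts()})")

ids = [t.voxel_id for t in ann.live_tags()]
X, y = training_table(ann, compute_features_at(vol, ids, bank))
model = train_classifier(ClassifierSpec("RFC", seed=0), X, y,
                         feature_names=bank.names, schema_hash=bank.hash)

pm = infer_volume(model, vol, bank)
gt8 = gt.astype(np.uint8)
print(f"Dice = {dice(pm, gt8):.4f}   RMSE = {rmse(pm, gt8):.4f}")
# Dice near 1 means the sparse strokes sufficed to recover the object;
# RMSE measures how confidently the probabilities separate the classes.
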