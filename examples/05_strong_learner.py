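"""Stack four weak classifiers under a gradient-boosting meta model.

The strong learner appends the weak learners' predicted probabilities to
the 56 base features (meta schema = 60 columns) and typically produces a
more decisive probability map than any single classifier.
"""

import numpy as np

from voxelearn import (
    ClassifierSpec,
    compute_features_at,
    default_bank,
    dice,
    infer_volume,
    simulate_strokes,
    standard_fixtures,
    train_classifier,
    train_strong,
)
from voxelearn.annotation import training_table

bank = default_bank()
_, vol, gt = standard_fixtures()["blob_noisy"]
ann = simulate_strokes(gt, seed=0)
ids = [t.voxel_id for t in ann.live_tags()]
X, y = training_table(ann, compute_features_at(vol, ids, bank))

rfc = train_classifier(ClassifierSpec("RFC", seed=0), X, y,
                       feature_names=bank.names, schema_hash=bank.hash)
strong = train_strong(X, y, seed=0, feature_names=bank.names, schema_hash=bank.hash)
print(f"weak learners: {sorted(strong.weak)}; meta columns: {strong.meta.n_features}")

gt8 = gt.astype(np.uint8)
pm_rfc, pm_strong = infer_volume(rfc, vol, bank), infer_volume(strong, vol, bank)
mid = lambda p: float(((p.data > 0.2) & (p.data < 0.8)).mean())
print(f"RFC:    Dice {dice(pm_rfc, gt8):.4f}, undecided voxels (0.2<p<0.8): {mid(pm_rfc):.4%}")
print(f"strong: Dice {dice(pm_strong, gt8):.4f}, undecided voxels (0.2<p<0.8): {mid(pm_strong):.4%}")
# The strong learner pushes probabilities toward 0/1: fewer undecided voxels.
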