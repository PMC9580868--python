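import warnings

import numpy as np
import pytest

import voxelearn as vx
from voxelearn.annotation import training_table
from voxelearn.synthetic_data import simulate_strokes, standard_fixtures

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def bank():
    return vx.default_bank()


@pytest.fixture(scope="session")
def fixtures():
    """The frozen phantom suite (blob_clean, blob_noisy, tubes_noisy)."""
    return standard_fixtures()


def _pipeline_on(fixtures, bank, name, n_pos=2, n_neg=2, seed=0):
    _, vol, gt = fixtures[name]
    ann = simulate_strokes(gt, n_pos_strokes=n_pos, n_neg_strokes=n_neg, seed=seed)
    ids = [t.voxel_id for t in ann.live_tags()]
    fm = vx.compute_features_at(vol, ids, bank)
    X, y = training_table(ann, fm)
    return vol, gt, ann, X, y


@pytest.fixture(scope="session")
def blob_noisy_training(fixtures, bank):
    """(vol, gt, ann, X, y) for blob_noisy with the standard 2+2 strokes."""
    return _pipeline_on(fixtures, bank, "blob_noisy")


@pytest.fixture(scope="session")
def blob_noisy_rfc(blob_noisy_training, bank):
    _, _, _, X, y = blob_noisy_training
    return vx.train_classifier(
        vx.ClassifierSpec("RFC", seed=0), X, y,
        feature_names=bank.names, schema_hash=bank.hash,
    )


@pytest.fixture(scope="session")
def separable_clusters():
    """Two well-separated Gaussian clusters, 50 samples each (seed 0)."""
    rng = np.random.default_rng(0)
    X0 = rng.normal(loc=-3.0, scale=0.5, size=(50, 5))
    X1 = rng.normal(loc=3.0, scale=0.5, size=(50, 5))
    X = np.vstack([X0, X1])
    y = np.array([0] * 50 + [1] * 50)
    return X, y
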