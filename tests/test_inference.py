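import numpy as np
import pytest

import voxelearn as vx
from voxelearn.annotation import training_table, xyz_to_id
from voxelearn.errors import SchemaError, ValidationError
from voxelearn.inference import (
    ProbabilityMap,
    default_probability_tf,
    grayscale_tf,
    infer_volume,
    iterate,
    log_transform,
    overlay,
)
from voxelearn.synthetic_data import simulate_strokes
from voxelearn.volume_io import TransferFunction, VolumeStack


@pytest.fixture(scope="module")
def clean_blob_run(fixtures, bank):
    """RFC trained with 20+20 strokes on the noiseless two-intensity blob."""
    _, vol, gt = fixtures["blob_clean"]
    ann = simulate_strokes(gt, n_pos_strokes=20, n_neg_strokes=20, seed=0)
    ids = [t.voxel_id for t in ann.live_tags()]
    fm = vx.compute_features_at(vol, ids, bank)
    X, y = training_table(ann, fm)
    model = vx.train_classifier(
        vx.ClassifierSpec("RFC", seed=0), X, y,
        feature_names=bank.names, schema_hash=bank.hash,
    )
    return vol, gt, ann, model


class TestInferVolume:
    def test_separable_phantom_recovers_ground_truth(self, clean_blob_run, bank):
        vol, gt, _, model = clean_blob_run
        pm = infer_volume(model, vol, bank)
        assert np.array_equal(pm.data >= 0.5, gt)
        assert vx.dice(pm, gt.astype(np.uint8)) == 1.0

    def test_probabilities_in_unit_interval(self, clean_blob_run, bank):
        vol, _, _, model = clean_blob_run
        pm = infer_volume(model, vol, bank)
        assert pm.data.min() >= 0.0 and pm.data.max() <= 1.0
        assert pm.dims == vol.dims

    def test_blockwise_inference_matches_monolithic(self, bank, blob_noisy_rfc, fixtures):
        _, vol, _ = fixtures["blob_noisy"]
        sub = VolumeStack(data=vol.data[:16, :16, :16])
        mono = infer_volume(blob_noisy_rfc, sub, bank)
        tiled = infer_volume(blob_noisy_rfc, sub, bank, block_shape=(8, 8, 8))
        assert np.max(np.abs(mono.data - tiled.data)) <= 1e-6

    def test_schema_mismatch_rejected(self, clean_blob_run):
        from voxelearn.feature_bank import FeatureBankSpec, FeatureDescriptor

        vol, _, _, model = clean_blob_run
        small = FeatureBankSpec((FeatureDescriptor("pixel_value", None),))
        with pytest.raises(SchemaError):
            infer_volume(model, vol, small)

    def test_agrees_with_sparse_prediction_at_tagged_voxels(self, clean_blob_run, bank):
        vol, _, ann, model = clean_blob_run
        pm = infer_volume(model, vol, bank)
        ids = [t.voxel_id for t in ann.live_tags()][:25]
        fm = vx.compute_features_at(vol, ids, bank)
        sparse_p = model.predict_proba(fm.values)
        dense_p = pm.data.reshape(-1)[ids]
        assert np.allclose(sparse_p, dense_p, atol=1e-6)


class TestLogTransform:
    def test_endpoints_and_floor(self):
        pm = ProbabilityMap(data=np.array([[[1.0, 0.0, 0.5]]]))
        lg = log_transform(pm)
        assert lg[0, 0, 0] == 0.0
        assert lg[0, 0, 1] == pytest.approx(np.log(1e-12))
        assert lg[0, 0, 2] == pytest.approx(np.log(0.5))

    def test_monotone_in_probability(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=50))
        lg = log_transform(ProbabilityMap(data=p.reshape(1, 1, -1))).ravel()
        assert np.all(np.diff(lg) >= 0)


class TestOverlay:
    def test_default_probability_tf_is_blue_to_red(self):
        tf = default_probability_tf()
        rgba = tf.evaluate(np.array([0.0, 1.0]))
        assert rgba[0, 0] == 0.0 and rgba[0, 2] == 1.0  # p=0: blue
        assert rgba[1, 0] == 1.0 and rgba[1, 2] == 0.0  # p=1: red

    def test_transparent_probability_layer_leaves_raw(self):
        rng = np.random.default_rng(1)
        raw = VolumeStack(data=rng.uniform(0, 255, size=(4, 4, 4)))
        pm = ProbabilityMap(data=rng.uniform(size=(4, 4, 4)))
        invisible = TransferFunction(points=[(0.0, 0.0, (0, 0, 1)), (1.0, 0.0, (1, 0, 0))])
        alone = overlay([(raw, grayscale_tf())])
        fused = overlay([(raw, grayscale_tf()), (pm, invisible)])
        assert np.allclose(alone.rgba, fused.rgba)

    def test_grayscale_identity_rendering(self):
        rng = np.random.default_rng(2)
        raw = VolumeStack(data=rng.uniform(0, 100, size=(3, 3, 3)))
        ov = overlay([(raw, grayscale_tf())])
        norm = raw.normalized()
        for c in range(3):
            assert np.allclose(ov.rgba[..., c], norm)

    def test_five_channels_rejected(self):
        raw = VolumeStack(data=np.zeros((2, 2, 2)))
        chans = [(raw, grayscale_tf())] * 5
        with pytest.raises(ValidationError):
            overlay(chans)

    def test_dim_mismatch_rejected(self):
        a = VolumeStack(data=np.zeros((2, 2, 2)))
        b = VolumeStack(data=np.zeros((3, 3, 3)))
        with pytest.raises(ValidationError):
            overlay([(a, grayscale_tf()), (b, grayscale_tf())])


class TestIterativeCorrection:
    def test_false_positive_corrections_do_not_hurt_dice(self, fixtures, bank):
        """A second tagging round marking false positives as negative never
        decreases Dice on the frozen blob fixture."""
        _, vol, gt = fixtures["blob_noisy"]
        ann = simulate_strokes(gt, n_pos_strokes=1, n_neg_strokes=1, radius=1.0, seed=0)
        spec = vx.ClassifierSpec("RFC", seed=0)
        m1 = iterate(spec, ann, vol, bank)
        pm1 = infer_volume(m1, vol, bank)
        d1 = vx.dice(pm1, gt.astype(np.uint8))
        fp = (pm1.data >= 0.5) & ~gt
        fp_ids = np.flatnonzero(fp.reshape(-1))[:40]
        m2 = iterate(spec, ann, vol, bank, new_tags=[(set(fp_ids.tolist()), "negative")])
        pm2 = infer_volume(m2, vol, bank)
        d2 = vx.dice(pm2, gt.astype(np.uint8))
        assert m2.metadata["iteration"] == 2
        assert d2 >= d1

    def test_empty_round_reproduces_model(self, fixtures, bank, blob_noisy_training):
        vol, gt, ann, X, y = blob_noisy_training
        spec = vx.ClassifierSpec("RFC", seed=0)
        m1 = iterate(spec, ann, vol, bank)
        m2 = iterate(spec, ann, vol, bank, new_tags=[])
        rng = np.random.default_rng(5)
        probe = rng.uniform(0, 255, size=(30, len(bank)))
        assert np.array_equal(m1.predict_proba(probe), m2.predict_proba(probe))

    def test_wrong_iteration_number_rejected(self, fixtures, bank):
        _, vol, gt = fixtures["blob_noisy"]
        ann = simulate_strokes(gt, seed=0)
        with pytest.raises(ValidationError):
            iterate(
                vx.ClassifierSpec("RFC", seed=0), ann, vol, bank,
                new_tags=[({0}, "negative")], iteration=5,
            )
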