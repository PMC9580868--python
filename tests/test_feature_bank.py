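"""Filter-bank correctness: brute-force neighbourhood oracles, tiling
self-consistency, and the bank's structural contracts."""

import numpy as np
import pytest

import voxelearn as vx
from voxelearn.annotation import xyz_to_id
from voxelearn.errors import ValidationError
from voxelearn.feature_bank import (
    FeatureBankSpec,
    FeatureDescriptor,
    compute_features_at,
    compute_features_full,
    default_bank,
    features_as_matrix,
)
from voxelearn.volume_io import VolumeStack


# ---------------------------------------------------------------------------
# independent oracle: np.pad + explicit window enumeration

def _gauss1d(k, scale=1.0):
    r = k // 2
    sigma = (k / 6.0) * scale
    w = np.exp(-(np.arange(-r, r + 1) ** 2) / (2 * sigma**2))
    return w / w.sum()


def _d1d(k):
    sigma = k / 6.0
    return -(np.arange(-(k // 2), k // 2 + 1) / sigma**2) * _gauss1d(k)


def _dd1d(k):
    r, sigma = k // 2, k / 6.0
    i = np.arange(-r, r + 1)
    h = ((i**2 - sigma**2) / sigma**4) * _gauss1d(k)
    return h - h.mean()


def _sep(a, b, c):
    return a[:, None, None] * b[None, :, None] * c[None, None, :]


def oracle_response(data, kind, k, z, y, x):
    """Direct windowed evaluation at one voxel of a symmetric-padded array."""
    r = k // 2
    pad = np.pad(data.astype(float), r, mode="symmetric")
    w = pad[z : z + k, y : y + k, x : x + k]
    g, d, h = _gauss1d(k), _d1d(k), _dd1d(k)
    if kind == "mean":
        return w.sum() / k**3
    if kind == "median":
        return float(np.sort(w.ravel())[w.size // 2])
    if kind == "minimum":
        return w.min()
    if kind == "maximum":
        return w.max()
    if kind == "range":
        return w.max() - w.min()
    if kind == "stddev":
        return float(np.sqrt(np.mean((w - w.mean()) ** 2)))
    if kind == "gaussian":
        return float((_sep(g, g, g) * w).sum())
    if kind == "difference_of_gaussians":
        g2 = _gauss1d(k, 2.0)
        return float(((_sep(g, g, g) - _sep(g2, g2, g2)) * w).sum())
    if kind == "laplacian_of_gaussian":
        ker = _sep(h, g, g) + _sep(g, h, g) + _sep(g, g, h)
        return float((ker * w).sum())
    if kind == "gradient_magnitude":
        comps = [(_sep(d, g, g) * w).sum(), (_sep(g, d, g) * w).sum(), (_sep(g, g, d) * w).sum()]
        return float(np.sqrt(sum(c**2 for c in comps)))
    if kind == "hessian_max_eigen":
        zz = (_sep(h, g, g) * w).sum()
        yy = (_sep(g, h, g) * w).sum()
        xx = (_sep(g, g, h) * w).sum()
        zy = (_sep(d, d, g) * w).sum()
        zx = (_sep(d, g, d) * w).sum()
        yx = (_sep(g, d, d) * w).sum()
        H = np.array([[zz, zy, zx], [zy, yy, yx], [zx, yx, xx]])
        return float(np.linalg.eigvalsh(H)[-1])
    raise AssertionError(kind)


class TestBankStructure:
    def test_default_bank_has_56_features(self):
        bank = default_bank()
        assert len(bank) == 56

    def test_pixel_value_is_feature_zero(self):
        assert default_bank().names[0] == "PIXEL_VALUE"

    def test_names_pairwise_distinct(self):
        names = default_bank().names
        assert len(set(names)) == 56

    def test_json_round_trip(self):
        bank = default_bank()
        assert FeatureBankSpec.from_json(bank.to_json()).names == bank.names

    def test_invalid_descriptors_rejected(self):
        with pytest.raises(ValidationError):
            FeatureDescriptor("gaussian", 4)  # even kernel
        with pytest.raises(ValidationError):
            FeatureDescriptor("sobel", 3)


class TestConstantField:
    def test_constant_volume_responses(self, bank):
        vol = VolumeStack(data=np.full((9, 9, 9), 42.0))
        center = xyz_to_id(4, 4, 4, vol.dims)
        fm = compute_features_at(vol, [center], bank)
        row = dict(zip(bank.names, fm.values[0]))
        for name, value in row.items():
            kind = name.rsplit("_k", 1)[0]
            if kind in ("PIXEL_VALUE", "GAUSSIAN", "MEAN", "MEDIAN", "MINIMUM", "MAXIMUM"):
                assert value == pytest.approx(42.0, abs=1e-9), name
            else:
                assert value == pytest.approx(0.0, abs=1e-9), name


class TestOracleEquivalence:
    @pytest.mark.parametrize("kind", [k for k in vx.feature_bank.FILTER_KINDS])
    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_dense_matches_window_enumeration(self, kind, k):
        """Every filter equals direct neighbourhood enumeration on <=7^3
        windows (1e-6)."""
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 255, size=(9, 9, 9))
        vol = VolumeStack(data=data)
        spec = FeatureBankSpec((FeatureDescriptor(kind, k),))
        dense = compute_features_full(vol, spec)
        for z, y, x in [(4, 4, 4), (0, 0, 0), (8, 3, 1)]:
            expected = oracle_response(data, kind, k, z, y, x)
            assert dense[0, z, y, x] == pytest.approx(expected, abs=1e-6), (kind, k, z, y, x)

    def test_mean_k3_center_is_27_voxel_average(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(size=(5, 5, 5))
        vol = VolumeStack(data=data)
        spec = FeatureBankSpec((FeatureDescriptor("mean", 3),))
        fm = compute_features_at(vol, [xyz_to_id(2, 2, 2, vol.dims)], spec)
        assert fm.values[0, 0] == pytest.approx(data[1:4, 1:4, 1:4].mean())

    def test_max_filter_sees_bright_neighbour(self):
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 100.0
        vol = VolumeStack(data=data)
        spec = FeatureBankSpec((FeatureDescriptor("maximum", 3),))
        fm = compute_features_at(vol, [xyz_to_id(4, 3, 3, vol.dims)], spec)
        assert fm.values[0, 0] == 100.0


class TestDenseSparseAgreement:
    def test_pixel_value_plane_is_input(self, bank):
        rng = np.random.default_rng(1)
        vol = VolumeStack(data=rng.uniform(size=(8, 8, 8)))
        dense = compute_features_full(vol, bank)
        assert np.array_equal(dense[0], vol.data)

    def test_dense_sampled_equals_sparse_rows(self, bank):
        rng = np.random.default_rng(2)
        vol = VolumeStack(data=rng.uniform(0, 100, size=(12, 12, 12)))
        ids = rng.choice(vol.n_voxels, size=10, replace=False)
        fm = compute_features_at(vol, ids, bank)
        X = features_as_matrix(compute_features_full(vol, bank), bank)
        assert np.allclose(X[ids], fm.values, atol=1e-6)

    def test_out_of_bounds_id_rejected(self, bank):
        vol = VolumeStack(data=np.zeros((4, 4, 4)))
        with pytest.raises(ValidationError):
            compute_features_at(vol, [64], bank)


class TestTiling:
    def test_blockwise_equals_monolithic(self, bank):
        rng = np.random.default_rng(5)
        vol = VolumeStack(data=rng.uniform(0, 255, size=(16, 16, 16)))
        mono = compute_features_full(vol, bank)
        tiled = compute_features_full(vol, bank, block_shape=(8, 8, 8))
        assert np.max(np.abs(mono - tiled)) <= 1e-6

    def test_uneven_blocks_also_exact(self, bank):
        rng = np.random.default_rng(6)
        vol = VolumeStack(data=rng.uniform(size=(13, 11, 9)))
        mono = compute_features_full(vol, bank)
        tiled = compute_features_full(vol, bank, block_shape=(6, 7, 5))
        assert np.max(np.abs(mono - tiled)) <= 1e-6

    def test_block_below_halo_rejected(self, bank):
        vol = VolumeStack(data=np.zeros((16, 16, 16)))
        with pytest.raises(ValidationError):
            compute_features_full(vol, bank, block_shape=(4, 8, 8))


class TestSpatialProperties:
    def test_translation_equivariance(self, bank):
        """Shifting the structure shifts interior responses identically."""
        rng = np.random.default_rng(8)
        base = np.zeros((20, 20, 20))
        base[7:12, 7:12, 7:12] = rng.uniform(50, 100, size=(5, 5, 5))
        shifted = np.roll(base, 1, axis=2)  # +1 in x
        d0 = compute_features_full(VolumeStack(data=base), bank)
        d1 = compute_features_full(VolumeStack(data=shifted), bank)
        # compare deep-interior responses (away from any padding influence)
        assert np.allclose(d0[:, 7:12, 7:12, 7:11], d1[:, 7:12, 7:12, 8:12], atol=1e-9)

    def test_min_max_monotone_in_kernel_size(self):
        rng = np.random.default_rng(9)
        vol = VolumeStack(data=rng.uniform(0, 255, size=(13, 13, 13)))
        sizes = [3, 5, 7, 9, 11]
        mins = FeatureBankSpec(tuple(FeatureDescriptor("minimum", k) for k in sizes))
        maxs = FeatureBankSpec(tuple(FeatureDescriptor("maximum", k) for k in sizes))
        vid = [xyz_to_id(6, 6, 6, vol.dims)]
        mn = compute_features_at(vol, vid, mins).values[0]
        mx = compute_features_at(vol, vid, maxs).values[0]
        assert np.all(np.diff(mn) <= 1e-12)
        assert np.all(np.diff(mx) >= -1e-12)
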