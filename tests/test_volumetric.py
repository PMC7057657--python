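import numpy as np
import pytest
from scipy import ndimage

from shootseg import (
    OrganLabel,
    RfConfig,
    RfModel,
    ValidationError,
    VoxelGrid,
    compute_feature_bank,
    predict_volume,
    train_rf,
)
from shootseg.volumetric import DOG_RATIO, _TRUNCATE, channel_names

SPACING = (0.5, 0.5, 0.5)


def binary(vals):
    return VoxelGrid(vals.astype(np.uint8), SPACING, kind="binary_mask")


class TestFeatureBank:
    def test_channel_layout(self):
        names = channel_names((0.7, 1.0))
        assert len(names) == 44
        assert names[0] == "gauss_s0.7" and names[22] == "gauss_s1"

    def test_constant_volume_has_zero_derivatives(self):
        grid = binary(np.ones((12, 12, 12)))
        bank = compute_feature_bank(grid, scales=(1.0,))
        cols = dict(zip(bank.column_names, bank.features.T))
        np.testing.assert_allclose(cols["gauss_s1"], 1.0, atol=1e-6)
        for name in ("grad_mag_s1", "log_s1", "dog_s1"):
            np.testing.assert_allclose(cols[name], 0.0, atol=1e-6)

    def test_impulse_response_is_sampled_gaussian(self):
        vals = np.zeros((21, 21, 21))
        vals[10, 10, 10] = 1
        mask = np.ones_like(vals, dtype=bool)
        bank = compute_feature_bank(binary(vals), scales=(1.0,), mask=mask)
        smoothed = bank.features[:, 0].reshape(21, 21, 21)
        # separable sampled-Gaussian kernel, same truncation
        sigma = 1.0 / SPACING[0]
        r = int(_TRUNCATE * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        expected = np.einsum("i,j,k->ijk", k1, k1, k1)
        np.testing.assert_allclose(
            smoothed[10 - r : 10 + r + 1, 10 - r : 10 + r + 1, 10 - r : 10 + r + 1],
            expected,
            atol=1e-6,
        )
        assert smoothed.sum() == pytest.approx(1.0, abs=1e-3)

    def test_matches_dense_convolution_oracle(self):
        # separable implementation vs direct 3D kernel convolution on a small grid
        rng = np.random.default_rng(0)
        vals = (rng.random((24, 24, 24)) < 0.2).astype(float)
        bank = compute_feature_bank(binary(vals), scales=(1.6,))
        sigma = 1.6 / SPACING[0]
        r = int(_TRUNCATE * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        dense = ndimage.convolve(vals, np.einsum("i,j,k->ijk", k1, k1, k1), mode="nearest")
        got = np.zeros_like(vals)
        idx = bank.mask_indices
        got[idx[:, 0], idx[:, 1], idx[:, 2]] = bank.features[:, 0]
        np.testing.assert_allclose(got[idx[:, 0], idx[:, 1], idx[:, 2]],
                                   dense[idx[:, 0], idx[:, 1], idx[:, 2]], rtol=1e-6, atol=1e-9)

    def test_blob_derivatives_match_finite_differences(self):
        # Gaussian blob: compare gradient/Laplacian channels at the centre
        # region against centred differences of the smoothed field
        n = 33
        c = (n - 1) / 2
        x = np.arange(n)
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        blob = np.exp(-((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2) / (2 * 4.0**2))
        grid = VoxelGrid((blob > 0.2).astype(np.uint8), SPACING, kind="binary_mask")
        mask = np.zeros_like(blob, dtype=bool)
        mask[10:23, 10:23, 10:23] = True
        bank = compute_feature_bank(grid, scales=(1.6,), mask=mask)
        sigma_vox = 1.6 / SPACING[0]
        smoothed = ndimage.gaussian_filter(
            grid.values.astype(float), sigma_vox, mode="nearest", truncate=_TRUNCATE
        )
        h = SPACING[0]

        def fd4(field, axis):
            # 4th-order centred difference; mask is far from the boundary
            f1, f_1 = np.roll(field, -1, axis), np.roll(field, 1, axis)
            f2, f_2 = np.roll(field, -2, axis), np.roll(field, 2, axis)
            return (-f2 + 8 * f1 - 8 * f_1 + f_2) / (12 * h)

        grad_mag = np.sqrt(sum(fd4(smoothed, ax) ** 2 for ax in range(3)))
        cols = dict(zip(bank.column_names, bank.features.T))
        idx = bank.mask_indices
        got = cols["grad_mag_s1.6"]
        want = grad_mag[idx[:, 0], idx[:, 1], idx[:, 2]]
        scale = np.abs(want).max()
        np.testing.assert_allclose(got / scale, want / scale, atol=1e-3)

    def test_axis_permutation_equivariance_of_eigen_channels(self):
        rng = np.random.default_rng(1)
        vals = (rng.random((16, 16, 16)) < 0.3).astype(np.uint8)
        grid = VoxelGrid(vals, SPACING, kind="binary_mask")
        bank = compute_feature_bank(grid, scales=(1.0,))
        perm_grid = VoxelGrid(vals.transpose(2, 0, 1), SPACING, kind="binary_mask")
        perm_bank = compute_feature_bank(perm_grid, scales=(1.0,))
        names = bank.column_names
        eig_cols = [i for i, n in enumerate(names) if "_eig" in n]
        orig = {tuple(i): f for i, f in zip(bank.mask_indices, bank.features[:, eig_cols])}
        for pidx, feats in zip(perm_bank.mask_indices, perm_bank.features[:, eig_cols]):
            z, x, y = pidx  # inverse of transpose(2, 0, 1)
            np.testing.assert_allclose(feats, orig[(x, y, z)], rtol=1e-5, atol=1e-8)

    def test_mass_preserved_for_interior_blob(self):
        vals = np.zeros((40, 40, 40))
        vals[17:23, 17:23, 17:23] = 1
        mask = np.ones_like(vals, dtype=bool)
        bank = compute_feature_bank(binary(vals), scales=(1.0,), mask=mask)
        total = bank.features[:, 0].sum()
        assert total == pytest.approx(vals.sum(), rel=0.005)

    def test_rejects_non_binary_input(self):
        grid = VoxelGrid(np.random.default_rng(0).random((8, 8, 8)), SPACING, kind="intensity")
        with pytest.raises(ValidationError):
            compute_feature_bank(grid)


def plate_and_rod_volume():
    """A thin plate plus a thin rod, labeled leaf/stem — separable geometry."""
    vals = np.zeros((40, 40, 40), dtype=np.uint8)
    vals[5:35, 5:35, 10] = int(OrganLabel.LEAF)
    vals[20, 20, 15:38] = int(OrganLabel.STEM)
    vals[19, 20, 15:38] = int(OrganLabel.STEM)
    return VoxelGrid(vals, SPACING, kind="label")


@pytest.fixture(scope="module")
def toy():
    labels = plate_and_rod_volume()
    mask_grid = VoxelGrid((labels.values != 0).astype(np.uint8), SPACING, kind="binary_mask")
    bank = compute_feature_bank(mask_grid, scales=(0.7, 1.6))
    return labels, bank


class TestRandomForest:

    def test_plate_vs_rod_out_of_bag_accuracy(self, toy):
        labels, bank = toy
        model = train_rf(bank, labels, RfConfig(seed=0))
        assert model.metadata["oob_score"] >= 0.95

    def test_training_grid_resubstitution_beats_oob(self, toy):
        labels, bank = toy
        model = train_rf(bank, labels, RfConfig(seed=0))
        pred = predict_volume(model, bank)
        idx = bank.mask_indices
        acc = (
            pred.values[idx[:, 0], idx[:, 1], idx[:, 2]]
            == labels.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        ).mean()
        assert acc >= model.metadata["oob_score"]

    def test_deterministic_given_seed(self, toy):
        labels, bank = toy
        a = predict_volume(train_rf(bank, labels, RfConfig(seed=3)), bank)
        b = predict_volume(train_rf(bank, labels, RfConfig(seed=3)), bank)
        np.testing.assert_array_equal(a.values, b.values)

    def test_model_round_trip(self, toy, tmp_path):
        labels, bank = toy
        model = train_rf(bank, labels, RfConfig(seed=0))
        model.save(tmp_path / "rf.joblib")
        reloaded = RfModel.load(tmp_path / "rf.joblib")
        np.testing.assert_array_equal(
            predict_volume(model, bank).values, predict_volume(reloaded, bank).values
        )

    def test_single_class_training_rejected(self):
        vals = np.zeros((10, 10, 10), dtype=np.uint8)
        vals[2:8, 2:8, 5] = int(OrganLabel.LEAF)
        labels = VoxelGrid(vals, SPACING, kind="label")
        bank = compute_feature_bank(
            VoxelGrid((vals != 0).astype(np.uint8), SPACING, kind="binary_mask"),
            scales=(0.7,),
        )
        with pytest.raises(ValidationError):
            train_rf(bank, labels, RfConfig())

    def test_flower_voxels_excluded_from_training(self):
        labels = plate_and_rod_volume()
        labels.values[5:10, 5:10, 20] = int(OrganLabel.FLOWER)
        mask_grid = VoxelGrid((labels.values != 0).astype(np.uint8), SPACING, kind="binary_mask")
        bank = compute_feature_bank(mask_grid, scales=(0.7,))
        model = train_rf(bank, labels, RfConfig(seed=0))
        n_leafstem = int(np.isin(labels.values, (1, 2)).sum())
        assert model.metadata["n_train"] == n_leafstem

    def test_schema_mismatch_rejected(self, toy):
        labels, bank = toy
        model = train_rf(bank, labels, RfConfig(seed=0))
        other = compute_feature_bank(
            VoxelGrid((labels.values != 0).astype(np.uint8), SPACING, kind="binary_mask"),
            scales=(0.7,),
        )
        with pytest.raises(ValidationError):
            predict_volume(model, other)

    def test_empty_mask_leaves_grid_untouched(self, toy):
        labels, bank = toy
        model = train_rf(bank, labels, RfConfig(seed=0))
        empty = compute_feature_bank(
            VoxelGrid(np.zeros((6, 6, 6), dtype=np.uint8), SPACING, kind="binary_mask"),
            scales=(0.7, 1.6),
        )
        out = predict_volume(model, empty)
        assert out.values.sum() == 0
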