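import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shootseg import (
    DegenerateNeighborhoodError,
    LabeledPointCloud,
    ValidationError,
    covariance_eigenvalues,
    curvature,
    eigen_features,
    flatness,
    multiscale_features,
    radius_neighbors,
)
from shootseg.features import EigenTriple, batch_eigenvalues, curvature_flatness


def brute_force_neighbors(coords, q, d):
    dists = np.linalg.norm(coords - coords[q], axis=1)
    return set(np.flatnonzero(dists < d))


class TestRadiusNeighbors:
    def test_collinear_examples_with_strict_boundary(self):
        cloud = LabeledPointCloud(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]))
        assert set(radius_neighbors(cloud, 0, 1.5)) == {0, 1}
        # a point at distance exactly d is excluded
        assert set(radius_neighbors(cloud, 0, 1.0)) == {0}

    def test_matches_brute_force_on_random_cloud(self, rng):
        cloud = LabeledPointCloud(rng.uniform(0, 10, size=(500, 3)))
        for q in rng.integers(0, 500, size=5):
            got = set(radius_neighbors(cloud, int(q), 1.5))
            assert got == brute_force_neighbors(cloud.coords, int(q), 1.5)


class TestCovarianceEigenvalues:
    def test_collinear_points(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        eig = covariance_eigenvalues(pts)
        np.testing.assert_allclose(eig.as_array(), [0, 0, 5 / 3], atol=1e-12)

    def test_coplanar_square(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        eig = covariance_eigenvalues(pts)
        np.testing.assert_allclose(eig.as_array(), [0, 1 / 3, 1 / 3], atol=1e-12)

    def test_octahedron_is_isotropic(self):
        pts = np.array(
            [[1.0, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        )
        eig = covariance_eigenvalues(pts)
        np.testing.assert_allclose(eig.as_array(), [0.4, 0.4, 0.4], atol=1e-12)

    def test_single_point_is_degenerate(self):
        with pytest.raises(DegenerateNeighborhoodError):
            covariance_eigenvalues(np.zeros((1, 3)))

    def test_eigenvalues_scale_quadratically(self, rng):
        pts = rng.normal(size=(40, 3))
        base = covariance_eigenvalues(pts).as_array()
        scaled = covariance_eigenvalues(3.0 * pts).as_array()
        np.testing.assert_allclose(scaled, 9.0 * base, rtol=1e-10)


class TestDescriptors:
    def test_curvature_closed_forms(self):
        assert curvature(EigenTriple(0, 1 / 3, 1 / 3)) == 0
        assert curvature(EigenTriple(0.4, 0.4, 0.4)) == pytest.approx(1 / 3, abs=1e-15)
        assert curvature(EigenTriple(1, 4, 9)) == pytest.approx(1 / 14, abs=1e-15)
        assert curvature(EigenTriple(0, 0, 0)) == 0.0  # degenerate convention

    def test_flatness_floor_and_cap(self):
        assert flatness(0.0) == pytest.approx(math.log(0.015), abs=1e-12)
        assert flatness(1 / 3) == pytest.approx(math.log(1 / 3), abs=1e-12)
        assert flatness(0.015) == flatness(0.0)  # floor boundary
        with pytest.raises(ValidationError):
            flatness(0.5)

    def test_eigen_feature_formulas(self):
        assert eigen_features(EigenTriple(1, 1, 1)) == (1, 1, 1, 1)
        assert eigen_features(EigenTriple(0, 4, 4)) == (0, 1, 0, 0)
        f = eigen_features(EigenTriple(1, 4, 9))
        np.testing.assert_allclose(f, (1 / 6, 4 / 9, 1 / 6, 1 / 4), rtol=1e-14)

    @settings(max_examples=200, deadline=None)
    @given(
        st.tuples(
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
        )
    )
    def test_curvature_range_and_flatness_monotone(self, lams):
        l1, l2, l3 = sorted(lams)
        c = curvature(EigenTriple(l1, l2, l3))
        assert 0 <= c <= 1 / 3 + 1e-12
        r = flatness(min(c, 1 / 3))
        assert math.log(0.015) - 1e-12 <= r <= math.log(1 / 3) + 1e-12
        assert flatness(min(c + 0.01, 1 / 3)) >= r


class TestMultiscale:
    def test_default_table_has_24_columns(self, tiny_phantom):
        table = multiscale_features(tiny_phantom.cloud)
        assert table.matrix.shape == (len(tiny_phantom.cloud), 24)
        assert table.column_names[0] == "F1_r2" and table.column_names[-1] == "F4_r7"

    def test_rotation_and_translation_invariance(self, tiny_phantom, rng):
        # jitter off the voxel lattice: exact-lattice distances sit on the
        # strict radius boundary, where a rotation can flip membership
        cloud = LabeledPointCloud(
            tiny_phantom.cloud.coords + rng.normal(scale=1e-3, size=(len(tiny_phantom.cloud), 3))
        )
        base = multiscale_features(cloud, radii=(2.0, 4.0)).matrix
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = cloud.transformed(q, [5.0, -3.0, 11.0])
        rotated = multiscale_features(moved, radii=(2.0, 4.0)).matrix
        np.testing.assert_allclose(rotated, base, rtol=1e-8, atol=1e-10)

    def test_rows_match_per_point_pipeline(self, tiny_phantom, rng):
        # batched table equals neighbour-scan + covariance + features per point
        cloud = tiny_phantom.cloud
        table = multiscale_features(cloud, radii=(3.0,))
        for q in rng.integers(0, len(cloud), size=12):
            idx = sorted(brute_force_neighbors(cloud.coords, int(q), 3.0))
            if len(idx) < 4:
                expected = np.zeros(4)
            else:
                expected = eigen_features(covariance_eigenvalues(cloud.coords[idx]))
            np.testing.assert_allclose(table.matrix[int(q)], expected, rtol=1e-8, atol=1e-10)

    def test_sparse_neighbourhoods_yield_zero_rows(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
        table = multiscale_features(LabeledPointCloud(coords), radii=(2.0,))
        np.testing.assert_array_equal(table.matrix, np.zeros((3, 4)))

    def test_csv_export_round_trip(self, tiny_phantom, tmp_path):
        table = multiscale_features(tiny_phantom.cloud, radii=(2.0, 3.0))
        path = tmp_path / "features.csv"
        table.to_csv(path)
        header = path.read_text().splitlines()[0].split(",")
        assert header == table.column_names
        back = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(back, table.matrix, rtol=1e-9, atol=1e-12)


class TestBatchEigenvalues:
    def test_curvature_flatness_bounds(self, tiny_phantom):
        curv, flat = curvature_flatness(tiny_phantom.cloud, radius=3.0)
        assert ((curv >= 0) & (curv <= 1 / 3 + 1e-12)).all()
        assert ((flat >= math.log(0.015) - 1e-12) & (flat <= math.log(1 / 3) + 1e-12)).all()

    def test_batch_counts_match_neighbour_scan(self, rng):
        cloud = LabeledPointCloud(rng.uniform(0, 5, size=(200, 3)))
        _, counts = batch_eigenvalues(cloud, 1.0)
        for q in rng.integers(0, 200, size=10):
            assert counts[int(q)] == len(brute_force_neighbors(cloud.coords, int(q), 1.0))
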