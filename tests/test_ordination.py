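import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import furscent as fs
from furscent.dissimilarity import DistanceMatrix
from furscent.io import FingerprintError
from furscent.ordination import _disparities

from conftest import euclidean_dm


class TestPcoa:
    def test_line_recovery(self):
        """Points on a line give one positive eigenvalue and exact distances."""
        pts = np.array([0.0, 3.0, 7.0])
        res = fs.pcoa(euclidean_dm(pts))
        assert (res.eigenvalues > 0).sum() == 1
        assert res.imaginary_axes.shape[1] == 0
        rec = squareform(pdist(res.real_axes))
        np.testing.assert_allclose(rec, squareform(pdist(pts[:, None])), atol=1e-8)

    def test_eigenvalue_sum_is_trace(self, bc_distance):
        res = fs.pcoa(bc_distance)
        G = fs.gower_center(bc_distance)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(G), rel=1e-9)

    def test_duplicate_points_coincide(self):
        res = fs.pcoa(euclidean_dm([0.0, 0.0, 5.0]))
        np.testing.assert_allclose(res.real_axes[0], res.real_axes[1], atol=1e-8)

    def test_axes_centered(self, bc_distance):
        res = fs.pcoa(bc_distance)
        np.testing.assert_allclose(res.real_axes.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(res.imaginary_axes.mean(axis=0), 0.0, atol=1e-9)

    def test_rank_bound(self):
        """Distances from k-dim points yield at most k positive eigenvalues."""
        rng = np.random.default_rng(4)
        res = fs.pcoa(euclidean_dm(rng.normal(size=(12, 3))))
        assert (res.eigenvalues > 1e-9).sum() <= 3

    def test_single_sample_rejected(self):
        with pytest.raises(FingerprintError):
            fs.pcoa(DistanceMatrix(["a"], np.zeros((1, 1))))


@pytest.fixture(scope="module")
def mid_distance():
    """Bray-Curtis distances on a 32-sample synthetic dataset."""
    cfg = fs.SyntheticConfig(n_colonies=2, families_per_colony=8, seed=7)
    pre = fs.preprocess_pipeline(fs.generate_dataset(cfg))
    return fs.bray_curtis(pre.matrix)


class TestNmds:
    def test_perfect_embedding(self):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        res = fs.nmds(euclidean_dm(corners), k=2, restarts=4, seed=0)
        assert res.stress < 1e-4

    def test_rank_invariance(self, mid_distance):
        """A strictly increasing transform of distances leaves stress unchanged."""
        r1 = fs.nmds(mid_distance, restarts=4, seed=5)
        warped = DistanceMatrix(mid_distance.sample_ids, mid_distance.D ** 1.7)
        r2 = fs.nmds(warped, restarts=4, seed=5)
        assert abs(r1.stress - r2.stress) < 1e-4

    def test_determinism(self, bc_distance):
        r1 = fs.nmds(bc_distance, restarts=3, seed=9)
        r2 = fs.nmds(bc_distance, restarts=3, seed=9)
        assert r1.stress == r2.stress
        np.testing.assert_array_equal(r1.coordinates, r2.coordinates)

    def test_stress_trace_non_increasing(self, bc_distance):
        res = fs.nmds(bc_distance, restarts=3, seed=2)
        assert np.all(np.diff(res.stress_trace) <= 1e-12)

    def test_reported_stress_recomputable(self, bc_distance):
        res = fs.nmds(bc_distance, restarts=3, seed=2)
        assert fs.stress(res.coordinates, bc_distance) == pytest.approx(res.stress,
                                                                        abs=1e-8)

    def test_coordinates_normalized(self, bc_distance):
        res = fs.nmds(bc_distance, restarts=2, seed=1)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)
        rms = np.sqrt((pdist(res.coordinates) ** 2).mean())
        assert rms == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_ranks_rejected(self):
        D = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(FingerprintError, match="degenerate ranks"):
            fs.nmds(DistanceMatrix(list("abcde"), D), k=2, restarts=1, seed=0)

    def test_k_too_large_rejected(self, bc_distance):
        with pytest.raises(FingerprintError):
            fs.nmds(euclidean_dm([0.0, 1.0, 2.0]), k=2, restarts=1, seed=0)


class TestStress:
    def test_perfect_configuration_zero(self):
        pts = np.random.default_rng(0).normal(size=(8, 2))
        assert fs.stress(pts, euclidean_dm(pts)) == pytest.approx(0.0, abs=1e-9)

    def test_bounds_and_rotation_invariance(self, bc_distance):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(bc_distance.n, 2))
        s = fs.stress(X, bc_distance)
        assert 0 <= s <= 1
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert fs.stress(X @ R, bc_distance) == pytest.approx(s, abs=1e-10)

    def test_pava_pools_violator(self):
        """Hand-run PAVA: a single order violation is pooled to the mean."""
        config_d = np.array([1.0, 3.0, 2.0])  # violator in last pair
        order = np.array([0, 1, 2])           # target already sorted
        fitted = _disparities(config_d, order)
        np.testing.assert_allclose(fitted, [1.0, 2.5, 2.5])
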