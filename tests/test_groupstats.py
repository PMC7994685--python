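"""Cluster maps, sign-flip permutation inference, lag and variance checks."""

import numpy as np
import pytest

from aslparc.connectivity import ATANH_CLIP
from aslparc.groupstats import (cluster_mean_connectivity, contrast_clusters,
                                lag_profile, permutation_one_sample,
                                variance_contrast)
from aslparc.parcellation import Parcellation
from aslparc.preprocess import DeltaMSeries


@pytest.fixture
def tiny_parc(tiny_masks):
    labels = np.ones(tiny_masks.n_roi, dtype=int)
    labels[tiny_masks.n_roi // 2:] = 2
    return Parcellation(labels=labels, k=2, source="extrinsic")


class TestClusterMap:
    def _dm(self, masks, fill):
        data = np.zeros(masks.grid.shape + (len(fill[0]),))
        for idx, series in fill:
            data[idx] = series
        return DeltaMSeries(data=data, grid=masks.grid, dt_s=7.8)

    def test_identical_series_clip_to_max_z(self, tiny_masks, tiny_parc):
        t = np.sin(np.arange(12))
        data = np.zeros(tiny_masks.grid.shape + (12,))
        data[tiny_masks.gm] = t
        dm = DeltaMSeries(data=data, grid=tiny_masks.grid, dt_s=7.8)
        zmap, in_cluster = cluster_mean_connectivity(dm, tiny_masks, tiny_parc, 1)
        assert zmap.max() == pytest.approx(np.arctanh(ATANH_CLIP))
        assert in_cluster.sum() == (tiny_parc.labels == 1).sum()

    def test_orthogonal_series_give_zero(self, tiny_masks, tiny_parc):
        t = 8
        data = np.zeros(tiny_masks.grid.shape + (t,))
        a = np.array([1, -1, 1, -1, 1, -1, 1, -1], float)
        b = np.array([1, 1, -1, -1, 1, 1, -1, -1], float)
        data[tuple(tiny_masks.roi_index.T)] = a
        gm_out = tiny_masks.gm_minus_roi_index
        data[tuple(gm_out.T)] = b
        dm = DeltaMSeries(data=data, grid=tiny_masks.grid, dt_s=7.8)
        zmap, in_cluster = cluster_mean_connectivity(dm, tiny_masks, tiny_parc, 1)
        np.testing.assert_allclose(zmap[~in_cluster & (np.abs(zmap) < 1)], 0.0,
                                   atol=1e-12)

    def test_mean_z_of_05_and_09(self):
        # two cluster voxels correlating 0.5 and 0.9 with a target: mean z
        z = (np.arctanh(0.5) + np.arctanh(0.9)) / 2
        assert z == pytest.approx(1.0108, abs=2e-4)

    def test_empty_cluster_rejected(self, tiny_masks, tiny_parc):
        data = np.random.default_rng(0).standard_normal(tiny_masks.grid.shape + (8,))
        dm = DeltaMSeries(data=data, grid=tiny_masks.grid, dt_s=7.8)
        with pytest.raises(ValueError):
            cluster_mean_connectivity(dm, tiny_masks, tiny_parc, 9)


class TestPermutation:
    def test_three_positive_subjects_exact_p(self):
        # strictly positive maps: the identity flip is uniquely maximal
        maps = np.outer([1.0, 1.1, 1.3], np.ones(5)) + np.arange(5) * 0.1
        res = permutation_one_sample(maps, n_perm=5000)
        assert res.exact and res.n_perm == 8
        np.testing.assert_allclose(res.p, 1 / 8)

    def test_seed_reproducible_monte_carlo(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((15, 10))
        r1 = permutation_one_sample(maps, n_perm=200, seed=42)
        r2 = permutation_one_sample(maps, n_perm=200, seed=42)
        np.testing.assert_array_equal(r1.p, r2.p)
        assert not r1.exact

    def test_smallest_achievable_monte_carlo_p(self):
        rng = np.random.default_rng(2)
        maps = np.abs(rng.standard_normal((20, 3))) + 5  # hugely positive
        n_perm = 400
        res = permutation_one_sample(maps, n_perm=n_perm, seed=0)
        assert res.p.min() == pytest.approx(1 / (n_perm + 1))

    def test_exact_and_monte_carlo_agree(self):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((8, 6)) + 0.4
        exact = permutation_one_sample(maps, n_perm=5000)
        assert exact.exact
        mc = permutation_one_sample(maps, n_perm=255, seed=7)
        assert not mc.exact
        assert np.abs(exact.p - mc.p).max() < 2 / np.sqrt(255)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            permutation_one_sample(np.zeros((1, 4)))
        with pytest.raises(ValueError):
            permutation_one_sample(np.zeros((4, 4)), n_perm=0)


class TestContrast:
    def test_identical_maps_give_empty_masks(self):
        rng = np.random.default_rng(4)
        maps = rng.standard_normal((10, 20))
        res = contrast_clusters(maps, maps.copy(), n_perm=200, seed=0)
        assert not res.mask_a.any() and not res.mask_b.any()

    def test_strong_block_detected_on_correct_side(self):
        rng = np.random.default_rng(5)
        n, v = 20, 30
        maps_a = rng.standard_normal((n, v))
        maps_b = rng.standard_normal((n, v))
        maps_a[:, :8] += 5.0          # 5-sd effect in a block of voxels
        res = contrast_clusters(maps_a, maps_b, n_perm=1000, seed=1)
        assert res.mask_a[:8].all()
        assert not res.mask_b.any()

    def test_infinite_threshold_empties_masks(self):
        rng = np.random.default_rng(6)
        maps_a = rng.standard_normal((10, 5)) + 3
        maps_b = rng.standard_normal((10, 5))
        res = contrast_clusters(maps_a, maps_b, z_crit=np.inf, n_perm=100, seed=0)
        assert not res.mask_a.any() and not res.mask_b.any()

    def test_masks_always_disjoint(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            a = rng.standard_normal((8, 40))
            b = rng.standard_normal((8, 40))
            res = contrast_clusters(a, b, z_crit=0.5, n_perm=200, seed=trial,
                                    correction="none")
            assert not (res.mask_a & res.mask_b).any()

    def test_voxelwise_rule_without_correction(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((12, 25))
        b = rng.standard_normal((12, 25))
        a[:, 0] += 4
        res = contrast_clusters(a, b, n_perm=100, seed=0, correction="none")
        np.testing.assert_array_equal(res.mask_a, res.z_a >= res.z_crit)


class TestLagProfile:
    def test_shift_recovered(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal(300)   # weak autocorrelation: shift is sharp
        res = lag_profile(base, np.roll(base, -2), max_lag=5)
        assert abs(res.best_lag) == 2
        assert res.best_r > 0.9
        assert res.time_shifted

    def test_identity_has_zero_best_lag(self):
        rng = np.random.default_rng(10)
        a = np.cumsum(rng.standard_normal(200))
        res = lag_profile(a, a, max_lag=10)
        assert res.best_lag == 0
        assert res.best_r == pytest.approx(1.0)
        assert not res.time_shifted

    def test_independent_noise_small_crosscorrelation(self):
        rng = np.random.default_rng(11)
        t = 400
        a = rng.standard_normal(t)
        b = rng.standard_normal(t)
        res = lag_profile(a, b, max_lag=5)
        assert np.abs(res.xcorr).max() < 5 / np.sqrt(t)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lag_profile(np.zeros(10), np.zeros(10), max_lag=5)


class TestVarianceContrast:
    def _dms(self, masks, scale_cluster1, n_subjects=8, t=40, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.ones(masks.n_roi, int)
        labels[masks.n_roi // 2:] = 2
        parc = Parcellation(labels=labels, k=2, source="extrinsic")
        dms = []
        for _ in range(n_subjects):
            data = rng.standard_normal(masks.grid.shape + (t,))
            sel = masks.roi_index[labels == 1]
            data[tuple(sel.T)] *= scale_cluster1
            dms.append(DeltaMSeries(data=data, grid=masks.grid, dt_s=7.8))
        return dms, parc

    def test_identical_clusters_high_p(self, tiny_masks):
        dms, parc = self._dms(tiny_masks, 1.0)
        _, _, p = variance_contrast(dms, tiny_masks, parc)
        assert p > 0.05

    def test_planted_double_variance_detected(self, tiny_masks):
        dms, parc = self._dms(tiny_masks, np.sqrt(2.0), n_subjects=20)
        va, vb, p = variance_contrast(dms, tiny_masks, parc)
        assert p < 0.01
        assert va.mean() > vb.mean()

    def test_identical_data_returns_p_one(self, tiny_masks):
        labels = np.ones(tiny_masks.n_roi, int)
        labels[: tiny_masks.n_roi // 2] = 2
        parc = Parcellation(labels=labels, k=2, source="extrinsic")
        data = np.random.default_rng(1).standard_normal(tiny_masks.grid.shape + (20,))
        # make the two clusters see literally identical values
        idx1 = tiny_masks.roi_index[labels == 1]
        idx2 = tiny_masks.roi_index[labels == 2]
        data[tuple(idx2.T)] = data[tuple(idx1.T)]
        dms = [DeltaMSeries(data=data, grid=tiny_masks.grid, dt_s=7.8)] * 6
        _, _, p = variance_contrast(dms, tiny_masks, parc)
        assert p == 1.0

    def test_constant_series_has_zero_variance(self, tiny_masks):
        data = np.ones(tiny_masks.grid.shape + (10,)) * 4
        dms = [DeltaMSeries(data=data, grid=tiny_masks.grid, dt_s=7.8)] * 6
        labels = np.ones(tiny_masks.n_roi, int)
        labels[-2:] = 2
        parc = Parcellation(labels=labels, k=2, source="extrinsic")
        va, vb, p = variance_contrast(dms, tiny_masks, parc)
        np.testing.assert_array_equal(va, 0.0)
        assert p == 1.0

    def test_few_subjects_warns(self, tiny_masks):
        dms, parc = self._dms(tiny_masks, 1.0, n_subjects=4)
        with pytest.warns(UserWarning):
            variance_contrast(dms, tiny_masks, parc)
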