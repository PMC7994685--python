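"""Surround subtraction, smoothing and CompCor regression behaviour."""

import numpy as np
import pytest

from aslparc.io import ImageGrid, RawAslSeries
from aslparc.preprocess import (FWHM_TO_SIGMA, NuisanceBasis, PreprocessParams,
                                extract_nuisance_basis, preprocess_subject,
                                regress_nuisance, smooth, surround_subtract)
from conftest import series_from_frames


class TestSurroundSubtract:
    def test_hand_example(self):
        # controls 10 and 12 flank label 8 -> dM = (10+12)/2 - 8 = 3
        s = series_from_frames([10, 8, 12])
        dm = surround_subtract(s)
        assert dm.n_frames == 1
        np.testing.assert_allclose(dm.data[..., 0], 3.0)

    def test_linear_drift_cancels_exactly(self):
        t = np.arange(40, dtype=float)
        a, b, delta = 7.0, 0.31, 5.0
        frames = a + b * t
        frames[1::2] -= delta  # labels depressed by constant perfusion
        dm = surround_subtract(series_from_frames(frames))
        np.testing.assert_allclose(dm.data, delta, rtol=1e-12)

    @pytest.mark.parametrize("parity,t,expected", [
        ("control_first", 300, 149),   # labels 1..297 usable, 299 dropped
        ("label_first", 300, 149),     # labels 2..298 usable, 0 dropped
        ("control_first", 6, 2),
    ])
    def test_usable_label_count(self, parity, t, expected):
        frames = np.zeros(t)
        dm = surround_subtract(series_from_frames(frames, parity=parity))
        assert dm.n_frames == expected

    def test_dt_is_twice_tr(self):
        dm = surround_subtract(series_from_frames(np.zeros(10), tr=3.9))
        assert dm.dt_s == pytest.approx(7.8)

    def test_positive_sign_for_perfused_tissue(self):
        frames = np.full(10, 100.0)
        frames[1::2] -= 60.0
        dm = surround_subtract(series_from_frames(frames))
        assert (dm.data > 0).all()


class TestSmooth:
    def test_sigma_in_voxels(self):
        # fwhm 5 mm on 4 mm voxels: sigma = 5/2.3548 = 2.1233 mm = 0.5308 vox
        assert 5.0 * FWHM_TO_SIGMA == pytest.approx(2.12331, abs=2e-5)
        assert 5.0 * FWHM_TO_SIGMA / 4.0 == pytest.approx(0.53083, abs=1e-5)

    def test_fwhm_zero_is_identity(self):
        dm = surround_subtract(series_from_frames(np.arange(10.0)))
        out = smooth(dm, 0.0)
        np.testing.assert_array_equal(out.data, dm.data)

    def test_constant_volume_unchanged(self):
        grid = ImageGrid.isotropic((6, 6, 6), 4.0)
        dm = surround_subtract(series_from_frames(np.ones(8) * 3.5, grid=grid))
        out = smooth(dm, 5.0)
        np.testing.assert_allclose(out.data, dm.data, rtol=1e-12)

    def test_spatial_mean_preserved(self):
        grid = ImageGrid.isotropic((8, 8, 6), 4.0)
        rng = np.random.default_rng(0)
        raw = RawAslSeries(data=rng.normal(size=grid.shape + (6,)) + 10,
                           grid=grid, tr=3.9, parity="control_first")
        dm = surround_subtract(raw)
        out = smooth(dm, 5.0)
        np.testing.assert_allclose(out.data.mean(axis=(0, 1, 2)),
                                   dm.data.mean(axis=(0, 1, 2)), rtol=1e-3)

    def test_negative_fwhm_rejected(self):
        dm = surround_subtract(series_from_frames(np.zeros(6)))
        with pytest.raises(ValueError):
            smooth(dm, -1.0)


class TestCompCor:
    def _dm_with_common_series(self, masks, g, noise=1e-3, seed=0):
        rng = np.random.default_rng(seed)
        data = np.zeros(masks.grid.shape + (len(g),))
        data[masks.nuisance] = g + noise * rng.standard_normal(
            (len(masks.nuisance_index), len(g)))
        data[masks.gm] = 0.5 * g
        from aslparc.preprocess import DeltaMSeries
        return DeltaMSeries(data=data, grid=masks.grid, dt_s=7.8)

    def test_rank_one_structure_recovered(self, tiny_masks):
        rng = np.random.default_rng(1)
        g = rng.standard_normal(30)
        dm = self._dm_with_common_series(tiny_masks, g)
        basis = extract_nuisance_basis(dm, tiny_masks, r=1)
        r = np.corrcoef(basis.components[0], g)[0, 1]
        assert abs(r) > 0.99

    def test_pca_deterministic_up_to_sign(self, tiny_masks):
        rng = np.random.default_rng(2)
        g = rng.standard_normal(30)
        dm = self._dm_with_common_series(tiny_masks, g, noise=0.5)
        b1 = extract_nuisance_basis(dm, tiny_masks, r=3)
        b2 = extract_nuisance_basis(dm, tiny_masks, r=3)
        for c1, c2 in zip(b1.components, b2.components):
            assert np.allclose(c1, c2) or np.allclose(c1, -c2)

    def test_ica_components_standardized_and_ordered(self, tiny_masks):
        rng = np.random.default_rng(3)
        g = rng.standard_normal(40)
        dm = self._dm_with_common_series(tiny_masks, g, noise=0.5)
        basis = extract_nuisance_basis(dm, tiny_masks, r=2, method="ica", seed=4)
        np.testing.assert_allclose(basis.components.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(basis.components, axis=1), 1.0)

    def test_r_too_large_rejected(self, tiny_masks):
        dm = self._dm_with_common_series(tiny_masks, np.zeros(10) + 1e-6)
        with pytest.raises(ValueError):
            extract_nuisance_basis(dm, tiny_masks, r=10)

    def test_regression_removes_own_component(self, tiny_masks):
        rng = np.random.default_rng(4)
        g = rng.standard_normal(30)
        dm = self._dm_with_common_series(tiny_masks, g, noise=0.0)
        basis = extract_nuisance_basis(dm, tiny_masks, r=1)
        out = regress_nuisance(dm, basis)
        np.testing.assert_allclose(out.data[tiny_masks.gm], 0.0, atol=1e-8)

    def test_residuals_orthogonal_and_projection_idempotent(self, tiny_masks):
        rng = np.random.default_rng(5)
        from aslparc.preprocess import DeltaMSeries
        data = rng.standard_normal(tiny_masks.grid.shape + (25,))
        dm = DeltaMSeries(data=data, grid=tiny_masks.grid, dt_s=7.8)
        basis = NuisanceBasis(components=rng.standard_normal((3, 25)), method="pca", r=3)
        basis.components -= basis.components.mean(axis=1, keepdims=True)
        once = regress_nuisance(dm, basis)
        dots = np.abs(once.data.reshape(-1, 25) @ basis.components.T)
        scale = np.linalg.norm(once.data) * np.linalg.norm(basis.components, axis=1)
        assert dots.max() / scale.max() < 1e-8
        twice = regress_nuisance(once, basis)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_zero_components_rejected(self, tiny_masks):
        from aslparc.preprocess import DeltaMSeries
        dm = DeltaMSeries(data=np.zeros(tiny_masks.grid.shape + (10,)),
                          grid=tiny_masks.grid, dt_s=7.8)
        basis = NuisanceBasis(components=np.zeros((2, 10)), method="pca", r=2)
        with pytest.raises(ValueError, match="rank"):
            regress_nuisance(dm, basis)

    def test_compcor_removes_global_nuisance_on_synthetic(self, small_cohort):
        """Post-regression correlation between gm voxel series and the true
        physiological series drops below 0.1 in median."""
        cfg, masks, truth, dms = small_cohort
        dm = dms[0]
        g = truth.nuisance_signals[(0, 0)]
        # the nuisance term enters dM through the surround-subtraction stencil
        lab = np.arange(1, cfg.n_frames, 2)[:-1]
        g_dm = g[lab] - 0.5 * (g[lab - 1] + g[lab + 1])
        ts = dm.data[masks.gm & ~masks.roi]
        r = [abs(np.corrcoef(row, g_dm)[0, 1]) for row in ts[::17]]
        assert np.median(r) < 0.1


class TestPipelineComposition:
    def test_identity_params_equal_subtraction(self, small_cfg):
        from aslparc.simulate import make_masks, simulate_subject
        masks, truth = make_masks(small_cfg)
        raw = simulate_subject(small_cfg, 0, 0, masks, truth)
        out = preprocess_subject(raw, masks, PreprocessParams(fwhm_mm=0, compcor_r=0))
        np.testing.assert_array_equal(out.data, surround_subtract(raw).data)

    def test_default_provenance_has_three_steps(self, small_cohort):
        _, _, _, dms = small_cohort
        steps = [p["step"] for p in dms[0].provenance]
        assert steps == ["surround_subtract", "smooth", "compcor"]

    def test_default_output_finite_with_expected_frames(self, small_cohort):
        cfg, _, _, dms = small_cohort
        assert dms[0].n_frames == cfg.n_frames // 2 - 1
        assert np.isfinite(dms[0].data).all()
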