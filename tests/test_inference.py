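"""Group inference: two-sample-t oracle, smoothness estimation against a
known kernel, cluster correction behavior, and report formatting."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from dcnet.containers import DCMap, StatMap, VolumeMask
from dcnet.inference import (_rft_cluster_p, estimate_smoothness, fit_voxelwise_glm,
                             make_group_design, permutation_cluster_correct,
                             report_clusters, resel_counts, grf_cluster_correct,
                             GroupDesign)
from .conftest import full_mask


def maps_from_values(values, shape=(2, 2, 2)):
    """One DCMap per subject with every in-mask voxel set per-subject."""
    out = []
    for i, rows in enumerate(values):
        vol = np.asarray(rows, dtype=float).reshape(shape)
        out.append(DCMap(raw_degree=np.zeros(shape), standardized=vol,
                         threshold_r=0.25, subject_id=f"s{i}"))
    return out


def two_group_design(n_a, n_b):
    X = np.column_stack([
        np.r_[np.ones(n_a), np.zeros(n_b)],
        np.ones(n_a + n_b),
    ])
    return GroupDesign(X, ["group", "intercept"], [f"s{i}" for i in range(n_a + n_b)])


class TestVoxelwiseGlm:
    def test_textbook_two_sample_t(self):
        """{1,2,3} vs {4,5,6}: pooled two-sample t = -3.674."""
        vals = [[v] * 8 for v in (1, 2, 3, 4, 5, 6)]
        maps = maps_from_values(vals)
        stat = fit_voxelwise_glm(maps, two_group_design(3, 3), full_mask((2, 2, 2)))
        assert np.allclose(stat.tmap, -3.674, atol=1e-3)
        assert stat.df == 4

    def test_equals_pooled_t_everywhere(self, rng):
        """With no covariates the GLM contrast t matches scipy's
        pooled-variance two-sample t to 1e-10 at every voxel."""
        n_a, n_b, shape = 9, 11, (3, 3, 3)
        data = rng.standard_normal((n_a + n_b,) + shape)
        maps = maps_from_values(data.reshape(n_a + n_b, -1), shape)
        stat = fit_voxelwise_glm(maps, two_group_design(n_a, n_b), full_mask(shape))
        expected = stats.ttest_ind(data[:n_a], data[n_a:], axis=0).statistic
        assert np.allclose(stat.tmap, expected, atol=1e-10)

    def test_identical_groups_give_zero_t(self, rng):
        shape = (2, 2, 2)
        block = rng.standard_normal((5,) + shape)
        data = np.concatenate([block, block])
        maps = maps_from_values(data.reshape(10, -1), shape)
        stat = fit_voxelwise_glm(maps, two_group_design(5, 5), full_mask(shape))
        assert np.abs(stat.tmap).max() < 1e-8

    def test_label_swap_negates_t(self, rng):
        shape = (2, 2, 2)
        data = rng.standard_normal((12,) + shape)
        maps = maps_from_values(data.reshape(12, -1), shape)
        d1 = two_group_design(6, 6)
        X2 = d1.X.copy()
        X2[:, 0] = 1 - X2[:, 0]
        d2 = GroupDesign(X2, d1.columns, d1.subject_ids)
        t1 = fit_voxelwise_glm(maps, d1, full_mask(shape)).tmap
        t2 = fit_voxelwise_glm(maps, d2, full_mask(shape)).tmap
        assert np.allclose(t1, -t2, atol=1e-10)

    def test_covariate_design_from_cohort(self, effect_cohort):
        design = make_group_design(effect_cohort["cohort"])
        assert design.columns == ["group", "age_years", "sex", "intercept"]
        assert design.X.shape[0] == len(effect_cohort["cohort"])

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.r_[np.ones(4), np.zeros(4)],
                             np.r_[np.ones(4), np.zeros(4)],
                             np.ones(8)])
        with pytest.raises(ValueError, match="rank deficient"):
            GroupDesign(X, ["group", "dup", "intercept"], [f"s{i}" for i in range(8)])


class TestSmoothness:
    def smooth_noise_maps(self, rng, n, shape, fwhm_vox):
        sigma = fwhm_vox / np.sqrt(8 * np.log(2))
        maps = rng.standard_normal((n,) + shape)
        if fwhm_vox > 0:
            maps = ndimage.gaussian_filter(maps, sigma=(0,) + (sigma,) * 3)
        return maps.reshape(n, -1)

    def test_known_kernel_recovered(self, rng):
        """White noise smoothed with a 6 mm kernel on 3 mm voxels is
        estimated within 15% of 6 mm."""
        shape = (20, 20, 20)
        mask = full_mask(shape)
        resid = self.smooth_noise_maps(rng, 20, shape, fwhm_vox=2.0)
        fwhm_vox, resels = estimate_smoothness(resid[:, mask.data.ravel()], mask)
        fwhm_mm = fwhm_vox * 3.0
        assert np.all(np.abs(fwhm_mm - 6.0) / 6.0 < 0.15)
        assert resels > 0

    def test_monotone_in_applied_smoothing(self, rng):
        shape = (16, 16, 16)
        mask = full_mask(shape)
        est = []
        for f in (0.0, 2.0, 4.0):
            resid = self.smooth_noise_maps(rng, 10, shape, f)
            fwhm, _ = estimate_smoothness(resid, mask)
            est.append(fwhm.mean())
        assert est[0] < est[1] < est[2]

    def test_resel_counts_box(self):
        mask = full_mask((10, 10, 10))
        R = resel_counts(mask, np.array([2.0, 2.0, 2.0]))
        assert np.isclose(R[3], 9**3 / 8.0)
        assert np.isclose(R[0], 1.0)  # Euler characteristic of a solid box


class TestClusterCorrection:
    def test_null_tmap_gives_empty_table(self, rng):
        shape = (8, 8, 8)
        mask = full_mask(shape)
        stat = StatMap(tmap=np.zeros(shape), df=20, mask=mask, affine=np.eye(4),
                       residual_fwhm_mm=np.array([6.0, 6, 6]), resel_count=10.0)
        table = grf_cluster_correct(stat, mask)
        assert table.empty

    def test_corrected_p_monotone_in_extent(self):
        mask = full_mask((12, 12, 12))
        stat = StatMap(tmap=np.zeros((12, 12, 12)), df=30, mask=mask,
                       affine=np.diag([3.0, 3, 3, 1]),
                       residual_fwhm_mm=np.array([6.0, 6, 6]), resel_count=64.0)
        ps = [_rft_cluster_p(k, 2.75, stat) for k in (5, 20, 80, 300)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0 <= p <= 1 for p in ps)

    def test_permutation_seed_reproducible(self, effect_cohort, effect_dc_maps):
        mask = effect_cohort["mask"]
        design = make_group_design(effect_cohort["cohort"])
        t1 = permutation_cluster_correct(effect_dc_maps, design, mask,
                                         n_perm=120, seed=3)
        t2 = permutation_cluster_correct(effect_dc_maps, design, mask,
                                         n_perm=120, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_effect_found_by_both_methods(self, effect_cohort, effect_dc_maps):
        """GRF and permutation agree on the planted clusters (each GRF
        cluster overlaps a permutation cluster peak-wise)."""
        mask = effect_cohort["mask"]
        design = make_group_design(effect_cohort["cohort"])
        stat = fit_voxelwise_glm(effect_dc_maps, design, mask)
        grf = grf_cluster_correct(stat, mask)
        perm = permutation_cluster_correct(effect_dc_maps, design, mask,
                                           n_perm=200, seed=0)
        assert len(grf) >= 2 and len(perm) >= 2
        assert {"increase", "decrease"} <= set(grf.sign)
        grf_peaks = {(r.peak_i, r.peak_j, r.peak_k) for r in grf.itertuples()}
        perm_peaks = {(r.peak_i, r.peak_j, r.peak_k) for r in perm.itertuples()}
        assert grf_peaks & perm_peaks

    def test_low_n_perm_rejected(self, effect_cohort, effect_dc_maps):
        with pytest.raises(ValueError):
            permutation_cluster_correct(effect_dc_maps,
                                        make_group_design(effect_cohort["cohort"]),
                                        effect_cohort["mask"], n_perm=10, seed=0)


class TestReport:
    def make_table(self):
        return pd.DataFrame([
            dict(peak_x_mm=0, peak_y_mm=0, peak_z_mm=0, peak_i=0, peak_j=0, peak_k=0,
                 n_voxels=64, peak_t=9.5, sign="increase", corrected_p=0.01),
            dict(peak_x_mm=0, peak_y_mm=0, peak_z_mm=0, peak_i=1, peak_j=1, peak_k=1,
                 n_voxels=199, peak_t=-11.4, sign="decrease", corrected_p=0.001),
            dict(peak_x_mm=0, peak_y_mm=0, peak_z_mm=0, peak_i=2, peak_j=2, peak_k=2,
                 n_voxels=20, peak_t=4.0, sign="increase", corrected_p=0.04),
        ])

    def test_sorted_by_absolute_t_with_signed_values(self):
        out = report_clusters(self.make_table(), min_cluster_voxels=0)
        assert list(out.peak_t) == [-11.4, 9.5, 4.0]

    def test_min_extent_floor(self):
        out = report_clusters(self.make_table())  # default floor 50 voxels
        assert len(out) == 2 and out.n_voxels.min() >= 50

    def test_empty_table_passes_through(self):
        empty = self.make_table().iloc[:0]
        assert report_clusters(empty).empty

    def test_world_coordinates_from_affine(self, effect_cohort, effect_dc_maps):
        """Peak voxel indices map to world mm through the 3 mm affine."""
        mask = effect_cohort["mask"]
        design = make_group_design(effect_cohort["cohort"])
        stat = fit_voxelwise_glm(effect_dc_maps, design, mask)
        table = grf_cluster_correct(stat, mask)
        for row in table.itertuples():
            assert row.peak_x_mm == pytest.approx(row.peak_i * 3.0)
            assert row.peak_y_mm == pytest.approx(row.peak_j * 3.0)
            assert row.peak_z_mm == pytest.approx(row.peak_k * 3.0)
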