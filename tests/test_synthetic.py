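"""Phantom generator: atlas construction, phenotype sampling, rendering."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from brainage.synthetic import (
    AgeDistribution,
    CohortConfig,
    fwhm_to_sigma,
    load_atlas,
    load_cohort,
    make_atlas,
    records_to_frame,
    render_cohort,
    render_volume,
    sample_cohort,
    save_atlas,
    save_cohort,
)


class TestMakeAtlas:
    def test_basic_structure(self):
        atlas = make_atlas((32, 32, 32), 3, seed=1)
        assert sorted(atlas.roi_ids) == [1, 2, 3]
        # disjoint by construction of the label grid; every ROI non-empty
        counts = atlas.roi_voxel_counts()
        assert all(c > 0 for c in counts.values())
        assert np.all(atlas.brain_mask[atlas.label_grid > 0])

    def test_deterministic(self):
        a = make_atlas((32, 32, 32), 3, seed=1)
        b = make_atlas((32, 32, 32), 3, seed=1)
        assert np.array_equal(a.label_grid, b.label_grid)
        assert np.array_equal(a.brain_mask, b.brain_mask)

    def test_voxel_counts_sum_to_nonzero_labels(self):
        atlas = make_atlas((32, 32, 32), 6, seed=2)
        brute = int(np.sum(atlas.label_grid != 0))
        assert sum(atlas.roi_voxel_counts().values()) == brute

    def test_too_many_rois_raises(self):
        with pytest.raises(RuntimeError, match="grid"):
            make_atlas((8, 8, 8), 40, seed=0, max_tries=50)

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError):
            make_atlas((32, 32, 32), 2, seed=0)


class TestSampleCohort:
    def test_independence_at_zero_confounding(self):
        cfg = CohortConfig(
            n_subjects=200,
            age_distribution=AgeDistribution("uniform", 8, 12),
            site_age_confounding=0.0,
            seed=7,
        )
        recs = sample_cohort(cfg)
        assert len(recs) == 200
        ages = np.array([r.age for r in recs])
        sites = np.array([r.site for r in recs])
        assert abs(np.corrcoef(ages, sites)[0, 1]) < 0.15

    def test_full_confounding_splits_on_median(self):
        cfg = CohortConfig(n_subjects=100, n_sites=2, site_age_confounding=1.0, seed=3)
        recs = sample_cohort(cfg)
        ages = np.array([r.age for r in recs])
        sites = np.array([r.site for r in recs])
        median = np.median(ages)
        assert np.all(sites[ages < median] == 0)
        assert np.all(sites[ages > median] == 1)

    def test_uniform_mean_age(self):
        cfg = CohortConfig(
            n_subjects=1000,
            age_distribution=AgeDistribution("uniform", 8, 12),
            seed=5,
        )
        ages = np.array([r.age for r in sample_cohort(cfg)])
        assert abs(ages.mean() - 10.0) < 0.2

    def test_degenerate_age_range_raises(self):
        cfg = CohortConfig(age_distribution=AgeDistribution("uniform", 10, 10))
        with pytest.raises(ValueError, match="degenerate"):
            sample_cohort(cfg)

    def test_confound_dial_monotone_eta_squared(self):
        """Dependence of age on site grows monotonically with the dial."""

        def eta_squared(ages, sites):
            grand = ages.mean()
            ss_tot = np.sum((ages - grand) ** 2)
            ss_between = sum(
                np.sum(sites == s) * (ages[sites == s].mean() - grand) ** 2
                for s in np.unique(sites)
            )
            return ss_between / ss_tot

        etas = []
        for c in (0.0, 0.5, 1.0):
            cfg = CohortConfig(n_subjects=400, site_age_confounding=c, seed=13)
            recs = sample_cohort(cfg)
            ages = np.array([r.age for r in recs])
            sites = np.array([r.site for r in recs])
            etas.append(eta_squared(ages, sites))
        assert etas[0] < etas[1] < etas[2]
        assert etas[0] < 0.05 and etas[2] > 0.6


class TestRenderVolume:
    def _plain_config(self, **kw):
        base = dict(
            grid_shape=(16, 16, 16),
            noise_sd=0.0,
            smoothing_fwhm=0.0,
            site_offsets=(0.0, 0.0),
            sex_effect=0.0,
            roi_age_slopes={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0},
        )
        base.update(kw)
        return CohortConfig(**base)

    def test_no_age_pathway_gives_identical_volumes(self, atlas16):
        cfg = self._plain_config()
        recs = sample_cohort(dataclasses.replace(cfg, n_subjects=2, seed=1))
        recs[0].age, recs[1].age = 9.0, 16.0
        rng = np.random.default_rng(0)
        v1 = render_volume(recs[0], atlas16, cfg, rng)
        v2 = render_volume(recs[1], atlas16, cfg, rng)
        # same sex/site enforced for a clean comparison
        assert recs[0].site == recs[1].site or cfg.site_offsets[0] == cfg.site_offsets[1]
        np.testing.assert_array_equal(v1.data, v2.data)

    def test_linear_slope_formula(self, atlas16):
        """0.01/yr in ROI 1 only: a 10y-vs-8y difference image is exactly
        0.02 inside ROI 1 (both channels, signs opposed) and 0 elsewhere."""
        cfg = self._plain_config(roi_age_slopes={1: 0.01, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0})
        recs = sample_cohort(dataclasses.replace(cfg, n_subjects=2, seed=1))
        for r, age in zip(recs, (10.0, 8.0)):
            r.age = age
            r.sex = 0
            r.site = 0
        rng = np.random.default_rng(0)
        v10 = render_volume(recs[0], atlas16, cfg, rng)
        v8 = render_volume(recs[1], atlas16, cfg, rng)
        diff = v10.data - v8.data
        roi1 = atlas16.roi_mask(1)
        np.testing.assert_allclose(diff[0][roi1], 0.02, atol=1e-6)  # GM
        np.testing.assert_allclose(diff[1][roi1], -0.02, atol=1e-6)  # WM negated
        assert np.all(diff[:, ~roi1] == 0)

    def test_nonnegative_and_masked(self, atlas16):
        cfg = CohortConfig(noise_sd=0.2, smoothing_fwhm=3.0)
        recs = sample_cohort(dataclasses.replace(cfg, n_subjects=3, seed=9))
        vols = render_cohort(recs, atlas16, cfg)
        assert vols.min() >= 0
        assert vols.max() <= 1
        assert np.all(vols[:, :, ~atlas16.brain_mask] == 0)

    def test_render_cohort_deterministic_and_reorder_stable(self, atlas16):
        cfg = CohortConfig(n_subjects=4, seed=31)
        recs1 = sample_cohort(cfg)
        recs2 = sample_cohort(cfg)
        v1 = render_cohort(recs1, atlas16, cfg)
        v2 = render_cohort(recs2, atlas16, cfg)
        np.testing.assert_array_equal(v1, v2)
        assert records_to_frame(recs1).equals(records_to_frame(recs2))

    def test_total_brain_volume_matches_image(self, atlas16):
        cfg = CohortConfig(n_subjects=2, seed=17)
        recs = sample_cohort(cfg)
        vols = render_cohort(recs, atlas16, cfg)
        expect = vols[0].mean(axis=0)[atlas16.brain_mask].sum() * cfg.voxel_size**3
        assert recs[0].total_brain_volume == pytest.approx(float(expect), rel=1e-5)

    def test_shape_mismatch_raises(self, atlas16):
        cfg = CohortConfig(grid_shape=(32, 32, 32), n_subjects=1, seed=0)
        recs = sample_cohort(cfg)
        with pytest.raises(ValueError, match="grid"):
            render_volume(recs[0], atlas16, cfg, np.random.default_rng(0))


class TestFwhmToSigma:
    def test_inverse_of_definition(self):
        assert fwhm_to_sigma(2.0 * np.sqrt(2.0 * np.log(2.0)), 1.0) == pytest.approx(1.0)

    def test_numeric_value(self):
        assert fwhm_to_sigma(8.0, 1.5) == pytest.approx(2.2649, abs=1e-4)

    @pytest.mark.parametrize("fwhm,voxel", [(0, 1), (8, 0), (-1, 1)])
    def test_nonpositive_raises(self, fwhm, voxel):
        with pytest.raises(ValueError):
            fwhm_to_sigma(fwhm, voxel)

    def test_impulse_half_max_width(self):
        """Smoothing a unit impulse with the returned sigma reproduces the
        requested FWHM, measured brute-force on the profile."""
        fwhm_mm, voxel = 8.0, 1.5
        sigma = fwhm_to_sigma(fwhm_mm, voxel)
        n = 101
        impulse = np.zeros(n)
        impulse[n // 2] = 1.0
        sm = ndimage.gaussian_filter1d(impulse, sigma)
        half = sm.max() / 2.0
        xs = np.arange(n, dtype=float)
        above = sm >= half
        lo, hi = xs[above][0], xs[above][-1]
        # linear interpolation at the crossings for sub-voxel accuracy
        def cross(i, j):
            return i + (half - sm[i]) / (sm[j] - sm[i]) * (j - i)

        width = cross(int(hi), int(hi) + 1) - cross(int(lo), int(lo) - 1)
        assert width == pytest.approx(fwhm_mm / voxel, rel=0.02)


class TestRoundTrip:
    def test_cohort_disk_round_trip(self, atlas16, tmp_path):
        cfg = CohortConfig(n_subjects=3, seed=23)
        recs = sample_cohort(cfg)
        vols = render_cohort(recs, atlas16, cfg)
        save_cohort(vols, recs, cfg, tmp_path / "cohort")
        vols2, recs2 = load_cohort(tmp_path / "cohort")
        np.testing.assert_array_equal(vols, vols2)
        assert records_to_frame(recs).equals(records_to_frame(recs2))

    def test_per_channel_layout_round_trip(self, atlas16, tmp_path):
        cfg = CohortConfig(n_subjects=2, seed=29)
        recs = sample_cohort(cfg)
        vols = render_cohort(recs, atlas16, cfg)
        save_cohort(vols, recs, cfg, tmp_path / "cohort", per_channel=True)
        assert (tmp_path / "cohort" / "manifest.csv").exists()
        vols2, recs2 = load_cohort(tmp_path / "cohort")
        np.testing.assert_array_equal(vols, vols2)

    def test_atlas_disk_round_trip(self, atlas16, tmp_path):
        save_atlas(atlas16, tmp_path / "atlas")
        atlas2 = load_atlas(tmp_path / "atlas")
        np.testing.assert_array_equal(atlas16.label_grid, atlas2.label_grid)
        np.testing.assert_array_equal(atlas16.brain_mask, atlas2.brain_mask)
        assert atlas16.roi_names == atlas2.roi_names
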