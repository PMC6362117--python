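"""MEDH feature extraction: magnitudes, regional variances, pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import special_ortho_group

from medh import features, phantom, registration
from medh.core_io import DisplacementField, Volume3D, warp, warp_labels
from medh.features import (
    SubjectBundle,
    extract_medh,
    hemisphere_of,
    magnitude_map,
    medh_matrix,
    regional_variance,
    tumor_overlap_fraction,
)

from .conftest import tumor_center


class TestMagnitudeMap:
    def test_pythagorean_triple(self):
        vec = np.zeros((4, 4, 4, 3))
        vec[...] = [3.0, 4.0, 12.0]
        fld = DisplacementField(vec, spacing=(1, 1, 1))
        np.testing.assert_allclose(magnitude_map(fld).data, 13.0)

    def test_zero_field(self):
        fld = DisplacementField(np.zeros((4, 4, 4, 3)), spacing=(1, 1, 1))
        assert np.all(magnitude_map(fld).data == 0)

    def test_rotation_invariance(self, rng):
        vec = rng.normal(size=(6, 6, 6, 3))
        rot = special_ortho_group.rvs(3, random_state=7)
        fld_a = DisplacementField(vec, spacing=(1, 1, 1))
        fld_b = DisplacementField(vec @ rot.T, spacing=(1, 1, 1))
        np.testing.assert_allclose(magnitude_map(fld_b).data,
                                   magnitude_map(fld_a).data, atol=1e-12)


class TestHemisphereOf:
    @pytest.mark.parametrize("name,expected", [
        ("Hippocampus_L", "left"),
        ("Precentral_R", "right"),
        ("Vermis_3", "non-hemispheric"),
        ("Midline_2", "non-hemispheric"),
    ])
    def test_suffix_convention(self, name, expected):
        assert hemisphere_of(name) == expected

    def test_unrecognized_suffix_warns(self):
        with pytest.warns(UserWarning, match="unrecognized"):
            assert hemisphere_of("Thalamus") == "non-hemispheric"


class TestRegionalVariance:
    @staticmethod
    def _table(mag_values, labels, **kw):
        shape = labels.shape
        mag = Volume3D(mag_values, spacing=(1, 1, 1))
        from medh.core_io import LabelVolume

        lv = LabelVolume(labels, spacing=(1, 1, 1))
        regions = pd.DataFrame({
            "region_id": sorted(set(labels.ravel()) - {0}),
        })
        regions["region_name"] = [f"Region_{i:02d}_L" for i in regions.region_id]
        regions["hemisphere"] = "left"
        return regional_variance(mag, lv, regions, **kw)

    def test_constant_magnitude_gives_zero(self):
        labels = np.ones((6, 6, 6), dtype=np.int32)
        out = self._table(np.full((6, 6, 6), 3.3), labels, min_voxels=1)
        assert out["medh_mm2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_value_region_sample_variance(self):
        """Magnitudes {1, 3}: sample variance with the n-1 convention is 2."""
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, 0] = labels[0, 0, 1] = 1
        mag = np.zeros((4, 4, 4))
        mag[0, 0, 0], mag[0, 0, 1] = 1.0, 3.0
        out = self._table(mag, labels, min_voxels=2)
        assert out["medh_mm2"].iloc[0] == pytest.approx(2.0)
        # population convention is exposed as a switch
        out0 = self._table(mag, labels, min_voxels=2, ddof=0)
        assert out0["medh_mm2"].iloc[0] == pytest.approx(1.0)

    def test_small_region_flagged_missing(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, :3] = 1
        out = self._table(np.random.default_rng(0).normal(size=(4, 4, 4)) ** 2,
                          labels, min_voxels=10)
        assert bool(out["missing"].iloc[0])
        assert np.isnan(out["medh_mm2"].iloc[0])

    def test_region_absent_from_labels_is_missing(self, small_atlas):
        mag = magnitude_map(DisplacementField(
            np.zeros(small_atlas.t1.shape + (3,)), small_atlas.t1.spacing))
        regions = pd.concat([small_atlas.regions, pd.DataFrame([
            {"region_id": 999, "region_name": "Ghost_L", "hemisphere": "left"}
        ])], ignore_index=True)
        out = regional_variance(mag, small_atlas.labels, regions)
        ghost = out[out["region_id"] == 999].iloc[0]
        assert bool(ghost["missing"]) and ghost["voxel_count"] == 0

    def test_empty_label_volume_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        with pytest.raises(ValueError, match="empty"):
            self._table(np.zeros((4, 4, 4)), labels)

    def test_scaling_law(self, atlas116):
        """Scaling the field by s multiplies every variance by s^2 exactly."""
        params = phantom.MassEffectParams(tumor_center(atlas116), 9.0, 3.0, 11.0)
        fld = phantom.mass_effect_field(params, atlas116.t1)
        s = 1.7
        scaled = DisplacementField(s * fld.vectors, fld.spacing, fld.origin)
        base = regional_variance(magnitude_map(fld), atlas116.labels,
                                 atlas116.regions)
        scl = regional_variance(magnitude_map(scaled), atlas116.labels,
                                atlas116.regions)
        np.testing.assert_allclose(scl["medh_mm2"].values,
                                   s**2 * base["medh_mm2"].values, rtol=1e-12)


class TestTumorOverlap:
    def test_empty_mask_gives_zero(self, small_atlas):
        frac = tumor_overlap_fraction(small_atlas.labels,
                                      np.zeros(small_atlas.t1.shape, dtype=bool))
        assert float(frac.max()) == 0.0

    def test_full_mask_gives_one(self, small_atlas):
        frac = tumor_overlap_fraction(small_atlas.labels,
                                      np.ones(small_atlas.t1.shape, dtype=bool))
        np.testing.assert_allclose(frac.values, 1.0)

    def test_half_covered_region(self, small_atlas):
        lab = small_atlas.labels.labels
        rid = int(small_atlas.regions["region_id"].iloc[0])
        sel = np.flatnonzero(lab.ravel() == rid)
        mask = np.zeros(lab.size, dtype=bool)
        mask[sel[: len(sel) // 2]] = True
        frac = tumor_overlap_fraction(small_atlas.labels, mask.reshape(lab.shape))
        assert frac[rid] == pytest.approx(0.5, abs=1.0 / len(sel) + 1e-9)


class TestExtractPipeline:
    @staticmethod
    def make_subject(atlas, d_max, lam=12.0, r_t=9.0, with_anat=True,
                     corrupt_img=False, seed=7):
        params = phantom.MassEffectParams(tumor_center(atlas), r_t, d_max, lam)
        timg, tmask = phantom.insert_tumor(atlas.t1, params, seed=seed)
        vec = phantom.mass_effect_field(params, atlas.t1).vectors.copy()
        if with_anat:
            vec += phantom.anatomical_variability_field(
                atlas.t1, atlas.brain_mask, seed=seed).vectors
        total = DisplacementField(vec, atlas.t1.spacing, atlas.t1.origin)
        if vec.any():
            img = warp(timg, total)
            msk = phantom.TumorMask(warp_labels(tmask.compartments, total))
        else:
            img, msk = timg, tmask
        if corrupt_img:
            img = phantom.corrupt(img, bias_amplitude=0.15, noise_sigma=2.0,
                                  seed=seed, brain_mask=img.data > 0)
        return SubjectBundle("s", img, msk, true_field=total,
                             tumor_in_atlas=tmask), total

    @staticmethod
    def truth_series(atlas, total):
        return regional_variance(magnitude_map(total), atlas.labels,
                                 atlas.regions,
                                 subject_id="s").set_index("region_id")["medh_mm2"]

    def test_bypass_equals_analytic_variance(self, atlas116):
        sub, total = self.make_subject(atlas116, 4.0)
        table, qc = extract_medh(sub, atlas116, use_true_field=True)
        est = table.set_index("region_id")["medh_mm2"]
        np.testing.assert_allclose(est.values,
                                   self.truth_series(atlas116, total).values,
                                   atol=1e-9)
        assert qc.mode == "ground_truth_bypass"

    def test_registration_noise_floor_without_deformation(self, atlas116):
        """No planted deformation: regional MEDH stays below 0.05 mm^2."""
        sub, _ = self.make_subject(atlas116, 0.0, with_anat=False)
        params = registration.RegistrationParams(similarity="mutual_information")
        table, qc = extract_medh(sub, atlas116, registration_params=params,
                                 run_preprocess=False)
        assert table["medh_mm2"].max() < 0.05
        assert qc.mode == "registered"

    def test_recovery_ranks_regions_correctly(self, atlas116):
        """Registration + extraction ranks regional variances like the truth."""
        sub, total = self.make_subject(atlas116, 4.0)
        params = registration.RegistrationParams(similarity="mutual_information")
        table, _ = extract_medh(sub, atlas116, registration_params=params,
                                run_preprocess=False)
        est = table.set_index("region_id")["medh_mm2"]
        tr = self.truth_series(atlas116, total)
        ok = np.isfinite(est) & np.isfinite(tr)
        rho = stats.spearmanr(est[ok], tr[ok]).statistic
        assert rho > 0.9

    def test_full_pipeline_with_preprocessing(self, atlas116):
        """Bias + noise + N4 + standardization: ranking survives, degraded by
        the standardization-induced variance floor."""
        sub, total = self.make_subject(atlas116, 4.0, corrupt_img=True)
        table, qc = extract_medh(sub, atlas116)
        est = table.set_index("region_id")["medh_mm2"]
        tr = self.truth_series(atlas116, total)
        ok = np.isfinite(est) & np.isfinite(tr)
        rho = stats.spearmanr(est[ok], tr[ok]).statistic
        assert rho > 0.4
        assert qc.inverse_consistency_mm < 0.5

    def test_masked_area_deformation_attenuated_toward_null(self, atlas116):
        """Inside the exclusion mask there is no data term, so the recovered
        deformation is the regularized extension of its surroundings: it
        understates the planted deformation there, and is near-null when
        nothing was planted."""
        from scipy.ndimage import binary_dilation

        from medh import preprocess

        for d_max in (4.0, 0.0):
            sub, total = self.make_subject(atlas116, d_max, corrupt_img=True)
            pre = preprocess.preprocess_subject(sub, atlas116)
            excl = binary_dilation(sub.tumor.combined, iterations=3)
            res = registration.register_pair(
                fixed=pre.t1, moving=atlas116.t1, fixed_exclusion_mask=excl,
                fixed_domain_mask=pre.brain_mask)
            inside = sub.tumor.combined
            est = res.forward.magnitude()[inside].mean()
            true = total.magnitude()[inside].mean()
            if d_max > 0:
                assert est < 0.75 * true
            else:
                assert est < 0.4

    def test_medh_matrix_pivot(self, small_atlas):
        rows = []
        for sid in ("a", "b"):
            fld = DisplacementField(
                np.zeros(small_atlas.t1.shape + (3,)), small_atlas.t1.spacing)
            t = regional_variance(magnitude_map(fld), small_atlas.labels,
                                  small_atlas.regions, subject_id=sid)
            rows.append(t)
        wide = medh_matrix(pd.concat(rows, ignore_index=True))
        assert wide.shape == (2, len(small_atlas.regions))
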