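"""Normative templates, z-maps, age adjustment, cluster extraction."""

import numpy as np
import pytest

import fcdkit as fk
from fcdkit.normative import default_sigma_floor


def fmap(data, modality="extension", spacing=(1.0, 1.0, 1.0)):
    return fk.FeatureMap(map=fk.Volume3D(data=np.asarray(data, float), spacing=spacing),
                         modality=modality)


class TestBuildTemplate:
    def test_identical_maps_zero_sigma(self, rng):
        m = fmap(rng.standard_normal((8, 8, 8)))
        tpl = fk.build_template([m, fmap(m.map.data.copy())])
        np.testing.assert_allclose(tpl.sigma.data, 0.0)
        np.testing.assert_allclose(tpl.mu.data, m.map.data)

    def test_two_point_sample_sd(self):
        tpl = fk.build_template([fmap(np.full((4, 4, 4), 10.0)),
                                 fmap(np.full((4, 4, 4), 14.0))])
        np.testing.assert_allclose(tpl.mu.data, 12.0)
        np.testing.assert_allclose(tpl.sigma.data, 2.0 * np.sqrt(2.0))

    def test_single_map_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            fk.build_template([fmap(rng.standard_normal((4, 4, 4)))])

    def test_mixed_modalities_rejected(self, rng):
        with pytest.raises(ValueError, match="mixed modalities"):
            fk.build_template([fmap(rng.standard_normal((4, 4, 4)), "junction"),
                               fmap(rng.standard_normal((4, 4, 4)), "extension")])

    def test_ages_length_mismatch_rejected(self, rng):
        maps = [fmap(rng.standard_normal((4, 4, 4))) for _ in range(3)]
        with pytest.raises(ValueError, match="ages length"):
            fk.build_template(maps, ages=[5.0, 6.0])

    def test_age_slope_recovery_synthetic_cohort(self):
        """value = 2 + 0.1*age + N(0, 0.05^2): OLS slope lands within 0.1 +/- 0.02."""
        rng = np.random.default_rng(31)
        ages = rng.uniform(5.0, 15.0, 30)
        maps = [fmap(2.0 + 0.1 * a + rng.normal(0.0, 0.05, (8, 8, 8))) for a in ages]
        tpl = fk.build_template(maps, ages=ages)
        interior = tpl.age_model.slope[2:-2, 2:-2, 2:-2]
        assert np.all(np.abs(interior - 0.1) <= 0.02)


class TestZMap:
    def test_patient_equals_mu_gives_zero(self, rng):
        m = fmap(rng.standard_normal((6, 6, 6)))
        tpl = fk.build_template([fmap(m.map.data + 1.0), fmap(m.map.data - 1.0)])
        zm = fk.zmap(fmap(tpl.mu.data.copy()), tpl)
        np.testing.assert_allclose(zm.z.data, 0.0)

    def test_two_sigma_deviation_scores_two(self, rng):
        base = rng.standard_normal((6, 6, 6))
        tpl = fk.build_template([fmap(base + 1.0), fmap(base - 1.0)])
        patient = fmap(tpl.mu.data + 2.0 * tpl.sigma.data)
        zm = fk.zmap(patient, tpl)
        np.testing.assert_allclose(zm.z.data, 2.0, atol=1e-9)

    def test_sigma_floor_semantics(self):
        tpl = fk.build_template([fmap(np.zeros((4, 4, 4))), fmap(np.zeros((4, 4, 4)))])
        patient = fmap(np.full((4, 4, 4), 0.01))
        zm = fk.zmap(patient, tpl, sigma_floor=1e-3)
        np.testing.assert_allclose(zm.z.data, 10.0)

    def test_modality_mismatch_rejected(self, rng):
        m = rng.standard_normal((4, 4, 4))
        tpl = fk.build_template([fmap(m), fmap(m + 1.0)])
        with pytest.raises(ValueError, match="modality mismatch"):
            fk.zmap(fmap(m, "junction"), tpl)


class TestAgeAdjustedZMap:
    def _linear_template(self, slope=0.1, noise=0.0, n=10, seed=2, shape=(6, 6, 6)):
        rng = np.random.default_rng(seed)
        ages = np.linspace(5.0, 15.0, n)
        maps = [fmap(2.0 + slope * a + rng.normal(0.0, noise, shape) * (noise > 0))
                for a in ages]
        return fk.build_template(maps, ages=ages), ages

    def test_predicted_value_scores_zero(self):
        tpl, ages = self._linear_template()
        age = 9.0
        patient = fmap(tpl.age_model.offset + tpl.age_model.slope * age)
        zm = fk.age_adjusted_zmap(patient, age, tpl, sigma_floor=1e-3)
        np.testing.assert_allclose(zm.z.data, 0.0, atol=1e-9)

    def test_offset_in_floor_units(self):
        """Noiseless cohort: a +3*floor offset scores exactly z = 3."""
        tpl, ages = self._linear_template()
        floor = 1e-3
        age = 9.0
        patient = fmap(tpl.age_model.offset + tpl.age_model.slope * age + 3.0 * floor)
        zm = fk.age_adjusted_zmap(patient, age, tpl, sigma_floor=floor)
        np.testing.assert_allclose(zm.z.data, 3.0, atol=1e-6)

    def test_missing_age_model_rejected(self, rng):
        m = rng.standard_normal((4, 4, 4))
        tpl = fk.build_template([fmap(m), fmap(m + 1.0)])
        with pytest.raises(ValueError, match="no age model"):
            fk.age_adjusted_zmap(fmap(m), 9.0, tpl)

    def test_out_of_range_age_warns(self):
        tpl, ages = self._linear_template()
        patient = fmap(tpl.age_model.offset + tpl.age_model.slope * 30.0)
        with pytest.warns(UserWarning, match="outside control range"):
            fk.age_adjusted_zmap(patient, 30.0, tpl, sigma_floor=1e-3)

    def test_lesion_patch_mean_z(self):
        """Planted +0.25 offset in a 5^3 patch scores ~5 residual SDs."""
        tpl, ages = self._linear_template(noise=0.05, n=30, seed=8, shape=(16, 16, 16))
        age = 10.0
        data = tpl.age_model.offset + tpl.age_model.slope * age
        data[5:10, 5:10, 5:10] += 0.25
        zm = fk.age_adjusted_zmap(fmap(data), age, tpl)
        patch_mean = zm.z.data[5:10, 5:10, 5:10].mean()
        assert abs(patch_mean - 5.0) <= 1.0


class TestSubtractionMap:
    def test_patient_equals_mu(self, rng):
        base = rng.standard_normal((6, 6, 6))
        tpl = fk.build_template([fmap(base + 1.0), fmap(base - 1.0)])
        out = fk.subtraction_map(fmap(tpl.mu.data.copy()), tpl)
        np.testing.assert_allclose(out.map.data, 0.0)

    def test_constant_offset(self, rng):
        base = rng.standard_normal((6, 6, 6))
        tpl = fk.build_template([fmap(base + 1.0), fmap(base - 1.0)])
        out = fk.subtraction_map(fmap(tpl.mu.data + 3.5), tpl)
        np.testing.assert_allclose(out.map.data, 3.5, atol=1e-12)

    def test_matches_voxel_loop_oracle(self, rng):
        base = rng.standard_normal((4, 4, 4))
        tpl = fk.build_template([fmap(base), fmap(base + rng.standard_normal((4, 4, 4)))])
        patient = fmap(rng.standard_normal((4, 4, 4)))
        out = fk.subtraction_map(patient, tpl)
        for idx in np.ndindex(4, 4, 4):
            assert out.map.data[idx] == pytest.approx(
                patient.map.data[idx] - tpl.mu.data[idx], abs=1e-12)


def zmap_from(data, spacing=(1.0, 1.0, 1.0)):
    return fk.ZMap(z=fk.Volume3D(data=np.asarray(data, float), spacing=spacing),
                   modality="junction", sigma_floor=1e-3)


class TestThresholdClusters:
    def test_all_zero_map_empty(self):
        cs = fk.threshold_clusters(zmap_from(np.zeros((10, 10, 10))), 1.96)
        assert len(cs) == 0

    def test_two_blocks(self):
        z = np.zeros((16, 16, 16))
        z[2:5, 2:5, 2:5] = 3.0
        z[10:13, 10:13, 10:13] = 4.0
        cs = fk.threshold_clusters(zmap_from(z), 1.96)
        assert len(cs) == 2
        assert [c.volume_mm3 for c in cs.clusters] == [27.0, 27.0]
        # sorted by peak z descending
        assert cs.clusters[0].peak_z == pytest.approx(4.0)

    def test_exclusion_mask_removes_cluster(self):
        z = np.zeros((16, 16, 16))
        z[2:5, 2:5, 2:5] = 3.0
        z[10:13, 10:13, 10:13] = 3.0
        excl = np.zeros((16, 16, 16), dtype=np.uint8)
        excl[9:14, 9:14, 9:14] = 1
        cs = fk.threshold_clusters(zmap_from(z), 1.96,
                                   exclusion=fk.BinaryMask(data=excl))
        assert len(cs) == 1

    def test_min_cluster_volume_drops_small(self):
        z = np.zeros((16, 16, 16))
        z[2:5, 2:5, 2:5] = 3.0
        z[10, 10, 10] = 5.0
        cs = fk.threshold_clusters(zmap_from(z), 1.96, min_cluster_mm3=5.0)
        assert len(cs) == 1 and cs.clusters[0].n_voxels == 27

    def test_higher_threshold_is_subset(self, rng):
        z = rng.standard_normal((20, 20, 20)) * 2.0
        lo = fk.threshold_clusters(zmap_from(z), 1.0)
        hi = fk.threshold_clusters(zmap_from(z), 2.5)
        assert np.all(lo.total_mask[hi.total_mask])

    def test_every_labeled_voxel_exceeds_threshold(self, rng):
        z = rng.standard_normal((20, 20, 20)) * 2.0
        cs = fk.threshold_clusters(zmap_from(z), 1.5)
        assert np.all(z[cs.total_mask] > 1.5)

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValueError, match="connectivity"):
            fk.threshold_clusters(zmap_from(np.zeros((4, 4, 4))), 2.0, connectivity=4)


class TestHeldOutCalibration:
    def test_pure_noise_suprathreshold_fraction(self):
        """Score a held-out noise control against an n=30 noise template.

        The nominal one-sided rate at z > 1.96 is 0.025; estimating mu
        and sigma from 30 controls inflates it (t-like tails), so the
        expected in-mask fraction lies in [0.015, 0.06].
        """
        rng = np.random.default_rng(42)
        maps = [fmap(rng.standard_normal((32, 32, 32))) for _ in range(31)]
        tpl = fk.build_template(maps[:30])
        zm = fk.zmap(maps[30], tpl)
        frac = float((zm.z.data > 1.96).mean())
        assert 0.015 <= frac <= 0.06
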