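"""Overlap metrics, ROC, cohort summaries, and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fcdkit as fk
from fcdkit.datasets import (WORKED_EXAMPLE_SUBJECTS, surgical_series,
                             synthetic_mask_pair)


def mask_from(data, spacing=(1.0, 1.0, 1.0)):
    return fk.BinaryMask(data=np.asarray(data, np.uint8), spacing=spacing)


class TestOverlapReport:
    def test_reference_subject_19(self):
        """|PRR|=1593, |PRC|=3096, overlap 1056 reproduces 34.1% and its DICE."""
        a, b = synthetic_mask_pair(1593, 3096, 1056)
        rep = fk.overlap_report(a, b)
        assert rep.percent_overlay == 34.1
        assert rep.dice == pytest.approx(2 * 1056 / (1593 + 3096))
        assert rep.overlap_mm3 == 1056.0

    def test_identical_masks(self, rng):
        data = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
        rep = fk.overlap_report(mask_from(data), mask_from(data.copy()))
        assert rep.dice == pytest.approx(1.0)
        assert rep.percent_overlay == 100.0

    def test_empty_reference_is_missing_not_zero(self, rng):
        det = mask_from((rng.random((6, 6, 6)) > 0.5).astype(np.uint8))
        empty = mask_from(np.zeros((6, 6, 6)))
        with pytest.warns(UserWarning, match="empty reference"):
            rep = fk.overlap_report(det, empty)
        assert np.isnan(rep.percent_overlay)

    def test_overlap_bounded_by_smaller_mask(self, rng):
        for _ in range(10):
            a = mask_from((rng.random((8, 8, 8)) > 0.6).astype(np.uint8))
            b = mask_from((rng.random((8, 8, 8)) > 0.6).astype(np.uint8))
            rep = fk.overlap_report(a, b)
            assert rep.overlap_mm3 <= min(rep.vol_a_mm3, rep.vol_b_mm3)

    def test_dice_symmetric_overlay_not(self, rng):
        a, b = synthetic_mask_pair(200, 600, 100)
        ab = fk.overlap_report(a, b)
        ba = fk.overlap_report(b, a)
        assert ab.dice == pytest.approx(ba.dice)
        assert ab.percent_overlay != ba.percent_overlay


class TestClusterOverlapTable:
    def _clusters(self, blocks, shape=(20, 20, 20)):
        z = np.zeros(shape)
        for (sl, val) in blocks:
            z[sl] = val
        zm = fk.ZMap(z=fk.Volume3D(data=z), modality="junction", sigma_floor=1e-3)
        return fk.threshold_clusters(zm, 2.0)

    def test_no_clusters(self):
        cs = self._clusters([])
        ref = mask_from(np.pad(np.ones((5, 5, 4)), ((0, 15), (0, 15), (0, 16))))
        table = fk.cluster_overlap_table(cs, ref)
        assert (table.n_overlapping, table.n_total) == (0, 0)
        assert table.percent_reference_covered == 0.0

    def test_cluster_inside_reference(self):
        cs = self._clusters([((slice(2, 5), slice(2, 5), slice(2, 5)), 3.0)])
        ref = np.zeros((20, 20, 20))
        ref[1:6, 1:6, 1:5] = 1  # 100 voxels containing the 27-voxel cluster
        table = fk.cluster_overlap_table(cs, mask_from(ref))
        assert (table.n_overlapping, table.n_total) == (1, 1)
        assert table.percent_reference_covered == 27.0

    def test_disjoint_cluster_not_counted(self):
        cs = self._clusters([((slice(2, 5), slice(2, 5), slice(2, 5)), 3.0),
                             ((slice(12, 15), slice(12, 15), slice(12, 15)), 3.0)])
        ref = np.zeros((20, 20, 20))
        ref[1:6, 1:6, 1:6] = 1
        table = fk.cluster_overlap_table(cs, mask_from(ref))
        assert (table.n_overlapping, table.n_total) == (1, 2)

    def test_empty_reference_rejected(self):
        cs = self._clusters([])
        with pytest.raises(ValueError, match="empty reference"):
            fk.cluster_overlap_table(cs, mask_from(np.zeros((20, 20, 20))))


class TestROC:
    def _setup(self, rng, shape=(32, 32, 32), ref_size=5):
        brain = np.ones(shape, dtype=np.uint8)
        ref = np.zeros(shape, dtype=np.uint8)
        ref[10:10 + ref_size, 10:10 + ref_size, 10:10 + ref_size] = 1
        return mask_from(brain), mask_from(ref)

    def test_perfect_detector(self, rng):
        brain, ref = self._setup(rng)
        score = fk.Volume3D(data=ref.data.astype(float))
        assert fk.roc_curve(score, ref, brain).auc == pytest.approx(1.0)

    def test_inverted_detector(self, rng):
        brain, ref = self._setup(rng)
        score = fk.Volume3D(data=1.0 - ref.data.astype(float))
        assert fk.roc_curve(score, ref, brain).auc == pytest.approx(0.0, abs=1e-9)

    def test_chance_level_random_scores(self, rng):
        brain, ref = self._setup(rng)
        score = fk.Volume3D(data=rng.uniform(0.0, 1.0, brain.shape))
        auc = fk.roc_curve(score, ref, brain).auc
        assert abs(auc - 0.5) <= 0.03

    def test_negation_flips_auc(self, rng):
        brain, ref = self._setup(rng)
        score = rng.standard_normal(brain.shape)
        n = 500
        auc = fk.roc_curve(fk.Volume3D(data=score), ref, brain, n).auc
        neg = fk.roc_curve(fk.Volume3D(data=-score), ref, brain, n).auc
        assert abs(auc + neg - 1.0) <= 1.0 / n + 1e-6

    def test_boosting_reference_scores_never_hurts(self, rng):
        brain, ref = self._setup(rng)
        score = rng.standard_normal(brain.shape)
        boosted = score + 0.5 * ref.data
        auc = fk.roc_curve(fk.Volume3D(data=score), ref, brain).auc
        auc_b = fk.roc_curve(fk.Volume3D(data=boosted), ref, brain).auc
        assert auc_b >= auc - 1e-9

    def test_matches_rank_auc_oracle(self, rng):
        """Trapezoid AUC at 10^4 thresholds tracks the Mann-Whitney AUC."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        brain, ref = self._setup(rng)
        score = fk.Volume3D(data=rng.standard_normal(brain.shape)
                            + 1.5 * ref.data)
        res = fk.roc_curve(score, ref, brain, n_thresholds=10_000)
        rank_auc = sklearn_metrics.roc_auc_score(ref.data.ravel(), score.data.ravel())
        assert abs(res.auc - rank_auc) <= 0.005

    def test_constant_map_degenerate(self, rng):
        brain, ref = self._setup(rng)
        score = fk.Volume3D(data=np.ones(brain.shape))
        with pytest.warns(UserWarning, match="constant score map"):
            res = fk.roc_curve(score, ref, brain)
        assert res.auc == 0.5

    def test_monotone_curve_and_endpoints(self, rng):
        brain, ref = self._setup(rng)
        score = fk.Volume3D(data=rng.standard_normal(brain.shape))
        res = fk.roc_curve(score, ref, brain)
        assert np.all(np.diff(res.tpr) >= 0) and np.all(np.diff(res.fpr) >= 0)
        assert (res.tpr[0], res.fpr[0]) == (0.0, 0.0)
        assert (res.tpr[-1], res.fpr[-1]) == (1.0, 1.0)

    def test_reference_outside_brain_rejected(self, rng):
        brain, ref = self._setup(rng)
        small_brain = mask_from(np.zeros(brain.shape))
        score = fk.Volume3D(data=rng.standard_normal(brain.shape))
        with pytest.raises(ValueError):
            fk.roc_curve(score, ref, small_brain)


class TestSummaries:
    def test_reference_cohort_means(self):
        """The 17 PRR and 23 PRC volumes summarise to their printed means."""
        df = surgical_series()
        mean_prr, lo, hi = fk.summarize_volumes(df["prr_mm3"].dropna())
        assert mean_prr == 1781
        assert (lo, hi) == (574.0, 4701.0)
        mean_prc, lo, hi = fk.summarize_volumes(df["prc_mm3"])
        assert mean_prc == 13863
        assert (lo, hi) == (2385.0, 52716.0)

    def test_single_value(self):
        assert fk.summarize_volumes([7.0]) == (7, 7.0, 7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fk.summarize_volumes([])


class TestPairedCompare:
    def test_identical_lists(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = fk.paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_known_differences(self):
        """d = {1,2,3,4}: t = 2.5 / (1.29099/2) = 3.8730, p ~ 0.0305."""
        t, p = fk.paired_compare([2.0, 4.0, 6.0, 8.0], [1.0, 2.0, 3.0, 4.0])
        assert t == pytest.approx(3.87298, abs=1e-4)
        assert p == pytest.approx(0.0305, abs=5e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            fk.paired_compare([1.0, 2.0], [1.0, 2.0, 3.0])


def holm_sidak_formula(p):
    """Independent step-down oracle for the Holm-Sidak adjustment."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj


class TestHolmSidak:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fk.holm_sidak([0.03]), [0.03])

    def test_two_p_worked_example(self):
        adj = fk.holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1.0 - 0.99 ** 2)  # 0.0199
        assert adj[1] == pytest.approx(0.04)

    def test_all_ones(self):
        np.testing.assert_allclose(fk.holm_sidak([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fk.holm_sidak([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_matches_step_down_formula(self, ps):
        np.testing.assert_allclose(fk.holm_sidak(ps), holm_sidak_formula(ps),
                                   atol=1e-12)


class TestZCutoff:
    def test_two_sided_p05_rounds_to_196(self):
        assert round(fk.z_cutoff(0.05), 2) == 1.96

    def test_one_sided(self):
        assert fk.z_cutoff(0.05, two_sided=False) == pytest.approx(1.6449, abs=1e-4)
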