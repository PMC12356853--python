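"""Agreement metrics between detections and reference masks.

Implements the evaluation layer of the detection study: DICE and
percent overlay between a detected mask and a reference (typically the
post-resection cavity, PRC, or the radiologist-outlined PRR),
per-cluster overlap bookkeeping, a voxel-level threshold-swept ROC with
AUC, cohort volume summaries, paired t-tests, and Holm-Sidak step-down
multiplicity adjustment.

Voxel-level ROC definitions: at each threshold t the detection is
{score > t}; the true positive rate is the detected fraction of the
reference mask, and the false positive rate is the detected fraction of
the brain *excluding* the reference.  Thresholds sweep evenly from the
maximum to the minimum score inside the brain; (0,0) and (1,1) are
appended and AUC is the trapezoid area of the (FPR, TPR) polyline.

Conventions: DICE = 2|A∩B| / (|A|+|B|) is symmetric; percent overlay
= 100 |A∩B| / |B| is not (it is the fraction of the *reference*
covered).  An empty reference makes overlay/DICE undefined — they are
reported as NaN with a warning, never as zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .normative import ClusterSet
from .volumes import BinaryMask, Volume3D, require_same_grid

logger = logging.getLogger("fcdkit")


@dataclass
class OverlapReport:
    """Volumes (mm^3), overlap, percent overlay and DICE for one mask pair."""

    vol_a_mm3: float        # detected / PRR
    vol_b_mm3: float        # reference / PRC
    overlap_mm3: float
    percent_overlay: float  # 100 * overlap / vol_b, one decimal; NaN if vol_b == 0
    dice: float             # 2 * overlap / (vol_a + vol_b); NaN if both empty


@dataclass
class ROCResult:
    """Threshold sweep with voxel-level TPR/FPR and trapezoid AUC."""

    thresholds: np.ndarray  # descending score values
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class ClusterOverlapTable:
    """Per-subject cluster bookkeeping against a reference mask."""

    n_overlapping: int       # clusters with >= 1 voxel inside the reference
    n_total: int
    percent_reference_covered: float  # by the union of all cluster voxels


# ---------------------------------------------------------------------------
# Overlap metrics

def overlap_report(detected: BinaryMask, reference: BinaryMask) -> OverlapReport:
    """DICE and percent overlay between a detected and a reference mask."""
    require_same_grid([detected, reference], "detected and reference masks")
    vv = detected.voxel_volume_mm3
    n_a = detected.n_voxels
    n_b = reference.n_voxels
    n_ov = int((detected.as_bool() & reference.as_bool()).sum())
    if n_b == 0:
        warnings.warn("empty reference mask: percent overlay undefined", stacklevel=2)
        percent = math.nan
    else:
        percent = round(100.0 * n_ov / n_b, 1)
    dice = 2.0 * n_ov / (n_a + n_b) if (n_a + n_b) > 0 else math.nan
    return OverlapReport(vol_a_mm3=n_a * vv, vol_b_mm3=n_b * vv,
                         overlap_mm3=n_ov * vv, percent_overlay=percent, dice=dice)


def cluster_overlap_table(clusters: ClusterSet, reference: BinaryMask) -> ClusterOverlapTable:
    """Count clusters touching the reference; coverage of the reference.

    A cluster counts as overlapping iff at least one of its voxels lies
    inside the reference mask.
    """
    if reference.n_voxels == 0:
        raise ValueError("empty reference mask")
    if clusters.label_map.shape != reference.shape:
        raise ValueError("clusters and reference are not on a common grid")
    ref = reference.as_bool()
    n_total = len(clusters)
    n_overlapping = sum(1 for c in clusters.clusters
                        if (clusters.cluster_mask(c.id) & ref).any())
    covered = int((clusters.total_mask & ref).sum())
    percent = round(100.0 * covered / reference.n_voxels, 1)
    return ClusterOverlapTable(n_overlapping=n_overlapping, n_total=n_total,
                               percent_reference_covered=percent)


# ---------------------------------------------------------------------------
# ROC

def roc_curve(score_map: Volume3D, reference: BinaryMask, brain_mask: BinaryMask,
              n_thresholds: int = 200) -> ROCResult:
    """Voxel-level ROC of a score map against a reference mask.

    The reference must lie inside the brain mask and be non-empty, and
    the brain must extend beyond the reference (otherwise FPR is
    undefined).  A constant score map yields a degenerate chance-level
    curve (AUC 0.5) with a warning.
    """
    require_same_grid([score_map, reference, brain_mask], "score map and masks")
    ref = reference.as_bool()
    brain = brain_mask.as_bool()
    if not ref.any():
        raise ValueError("empty reference mask")
    if (ref & ~brain).any():
        raise ValueError("reference mask extends outside the brain mask")
    neg = brain & ~ref
    if not neg.any():
        raise ValueError("brain mask minus reference is empty")

    scores = score_map.data
    in_brain = scores[brain]
    lo, hi = float(in_brain.min()), float(in_brain.max())
    if lo == hi:
        warnings.warn("constant score map: degenerate ROC, AUC 0.5", stacklevel=2)
        return ROCResult(thresholds=np.array([hi]), tpr=np.array([0.0, 1.0]),
                         fpr=np.array([0.0, 1.0]), auc=0.5)

    thresholds = np.linspace(hi, lo, int(n_thresholds))
    # detection predicate is strictly "greater than" the threshold;
    # count detected voxels per threshold via sorted-array bisection
    pos_sorted = np.sort(scores[ref])
    neg_sorted = np.sort(scores[neg])
    tpr = 1.0 - np.searchsorted(pos_sorted, thresholds, side="right") / pos_sorted.size
    fpr = 1.0 - np.searchsorted(neg_sorted, thresholds, side="right") / neg_sorted.size
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


# ---------------------------------------------------------------------------
# Cohort summaries and statistics

def summarize_volumes(volumes) -> tuple:
    """(mean rounded to nearest integer, min, max) of a list of mm^3 volumes."""
    volumes = [float(v) for v in volumes]
    if not volumes:
        raise ValueError("empty volume list")
    return (int(round(sum(volumes) / len(volumes))), min(volumes), max(volumes))


def paired_compare(metric_a, metric_b):
    """Classical paired t-test; two-sided p, n-1 degrees of freedom.

    Zero-variance differences (e.g. identical lists) are reported as
    t = 0, p = 1 with a warning rather than as an error.
    """
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d, d[0]) and np.isclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences: reporting t=0, p=1", stacklevel=2)
        return 0.0, 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def holm_sidak(p_values):
    """Holm-Sidak step-down adjusted p-values, in the original order.

    Sort ascending; adjusted_(i) = 1 - (1 - p_(i))^(m - i + 1); enforce
    monotonicity by running maximum; cap at 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D sequence")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def z_cutoff(alpha: float = 0.05, two_sided: bool = True) -> float:
    """Gaussian z cutoff for significance level ``alpha``.

    The two-sided p = 0.05 cutoff is 1.959964..., the conventional
    z > 1.96 threshold applied to the deviation maps.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    q = 1.0 - alpha / 2.0 if two_sided else 1.0 - alpha
    return float(sps.norm.ppf(q))
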