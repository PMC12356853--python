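"""Orchestration: subject feature extraction, detection, and study tables.

Ties the stages into the three detection pipelines (junction,
extension, thickness) and the evaluation study:

    T1 -> mean-normalise -> segment -> feature map -> z-map vs
    normative template -> suprathreshold clusters -> metrics

Every run is driven by a :class:`RunConfig` whose effective values are
persisted verbatim in the run manifest, so identical config + inputs
reproduce identical outputs (all stages are deterministic; stochastic
inputs carry their own seeds).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, normative, segmentation, volumes
from .features import FeatureMap, MODALITIES
from .normative import ClusterSet, NormativeTemplate, ZMap
from .volumes import BinaryMask, SmoothingSpec, Volume3D

logger = logging.getLogger("fcdkit")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject id."""


@dataclass
class RunConfig:
    """Effective configuration of one detection/evaluation run."""

    modality: str = "junction"
    z_threshold: float = normative.DEFAULT_Z_THRESHOLD
    fwhm_mm: float = 6.0
    connectivity: int = 26
    min_cluster_mm3: float = 0.0
    sigma_floor: float = None       # None -> robust default per template
    prob_threshold: float = 0.5
    exclusion_mask: str = None      # path to a NIfTI mask, optional
    seed: int = 0
    output_dir: str = None

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")

    @property
    def smoothing(self) -> SmoothingSpec:
        return SmoothingSpec(fwhm_mm=self.fwhm_mm)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class DetectionResult:
    feature: FeatureMap
    zmap: ZMap
    clusters: ClusterSet
    report: dict


# ---------------------------------------------------------------------------
# Feature extraction (shared by controls and patients)

def compute_feature_map(t1: Volume3D, brain_mask: BinaryMask,
                        cortical_mask: BinaryMask, modality: str,
                        config: RunConfig = None,
                        segmentation_result=None) -> FeatureMap:
    """One subject's feature map for one modality.

    The T1 is mean-normalised inside the brain mask before segmentation
    so the junction thresholds and the voxel values share a scale.  A
    precomputed :class:`~fcdkit.segmentation.TissueSegmentation` (e.g. a
    phantom's ground truth or external probability maps) can be passed
    to skip the GMM stage.
    """
    if config is None:
        config = RunConfig(modality=modality)
    t1n = volumes.normalize_by_mean(t1, brain_mask)
    if segmentation_result is None:
        seg = segmentation.segment_tissues(t1n, brain_mask, seed=config.seed,
                                           prob_threshold=config.prob_threshold)
    else:
        seg = segmentation_result
        if seg.stats is None:
            seg.stats = segmentation.tissue_stats(t1n, seg,
                                                  prob_threshold=config.prob_threshold)
    if modality == "junction":
        return features.junction_map(t1n, seg.stats, cortical_mask, config.smoothing)
    if modality == "extension":
        return features.extension_map(seg, cortical_mask, config.smoothing)
    if modality == "thickness":
        return features.thickness_map(seg)
    raise ValueError(f"unknown modality {modality!r}")


def build_cohort_template(subjects, modality: str, config: RunConfig = None,
                          ages=None) -> NormativeTemplate:
    """Normative template from a list of control subjects.

    ``subjects`` is a list of objects with ``t1``, ``brain_mask`` and
    ``cortical_mask`` attributes (e.g. :class:`~fcdkit.phantom.HeadPhantom`).
    """
    maps = [compute_feature_map(s.t1, s.brain_mask, s.cortical_mask, modality, config)
            for s in subjects]
    return normative.build_template(maps, ages=ages)


# ---------------------------------------------------------------------------
# Detection and evaluation

def run_detection(t1: Volume3D, brain_mask: BinaryMask, cortical_mask: BinaryMask,
                  template: NormativeTemplate, config: RunConfig = None,
                  age: float = None, exclusion: BinaryMask = None,
                  subject_id: str = "subject") -> DetectionResult:
    """Full single-subject detection for the configured modality."""
    if config is None:
        config = RunConfig(modality=template.modality)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"[{subject_id}] stage {name!r} failed: {exc}") from exc

    fmap = stage("features", compute_feature_map, t1, brain_mask, cortical_mask,
                 config.modality, config)
    if age is not None and template.age_model is not None:
        zm = stage("zmap", normative.age_adjusted_zmap, fmap, age, template,
                   config.sigma_floor)
    else:
        zm = stage("zmap", normative.zmap, fmap, template, config.sigma_floor)
    clusters = stage("clusters", normative.threshold_clusters, zm,
                     config.z_threshold, config.connectivity,
                     config.min_cluster_mm3, exclusion)
    report = {
        "subject": subject_id,
        "modality": config.modality,
        "z_threshold": config.z_threshold,
        "sigma_floor": zm.sigma_floor,
        "n_clusters": len(clusters),
        "clusters": clusters.to_rows(),
        "config": config.to_dict(),
    }
    return DetectionResult(feature=fmap, zmap=zm, clusters=clusters, report=report)


def run_evaluation(results, references, brain_masks, config: RunConfig = None,
                   score_maps=None) -> pd.DataFrame:
    """Per-subject metrics table against reference masks.

    Parameters
    ----------
    results : dict subject_id -> DetectionResult (or ClusterSet)
    references : dict subject_id -> BinaryMask (missing subjects are
        reported with a warning; the run continues)
    brain_masks : dict subject_id -> BinaryMask (for the ROC sweep)
    score_maps : optional dict subject_id -> Volume3D overriding the
        z-map as the ROC score image

    Returns one row per subject with cluster counts, percent coverage,
    DICE of the suprathreshold mask, and AUC.
    """
    rows = []
    for sid, res in results.items():
        clusters = res.clusters if isinstance(res, DetectionResult) else res
        ref = references.get(sid)
        if ref is None:
            warnings.warn(f"no reference mask for {sid}; metrics reported as missing",
                          stacklevel=2)
            rows.append({"subject": sid, "n_clusters_overlapping": np.nan,
                         "n_clusters_total": len(clusters),
                         "percent_reference_covered": np.nan,
                         "dice": np.nan, "auc": np.nan})
            continue
        table = evaluation.cluster_overlap_table(clusters, ref)
        detected = BinaryMask(data=clusters.total_mask.astype(np.uint8),
                              affine=ref.affine)
        overlap = evaluation.overlap_report(detected, ref)
        auc = np.nan
        score = None
        if score_maps is not None and sid in score_maps:
            score = score_maps[sid]
        elif isinstance(res, DetectionResult):
            score = res.zmap.z
        if score is not None and sid in brain_masks:
            auc = evaluation.roc_curve(score, ref, brain_masks[sid]).auc
        rows.append({
            "subject": sid,
            "n_clusters_overlapping": table.n_overlapping,
            "n_clusters_total": table.n_total,
            "percent_reference_covered": table.percent_reference_covered,
            "dice": overlap.dice,
            "auc": auc,
        })
    return pd.DataFrame(rows).set_index("subject")


# ---------------------------------------------------------------------------
# Run manifests

def write_manifest(path, config: RunConfig, inputs: dict = None) -> None:
    """Persist the effective config (and input identifiers) as JSON."""
    manifest = {"config": config.to_dict(), "inputs": inputs or {}}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path) -> RunConfig:
    manifest = json.loads(Path(path).read_text())
    return RunConfig.from_dict(manifest["config"])
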