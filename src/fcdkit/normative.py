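"""Normative templates, z-score maps, and candidate-cluster extraction.

For each modality a normative template holds the voxel-wise mean and
sample standard deviation of the feature map across a healthy control
cohort.  A patient map is scored voxel-wise as

    z = (patient - mu) / max(sigma, sigma_floor)

and thresholded (default z > 1.96, the two-sided p = 0.05 Gaussian
cutoff) to produce candidate clusters.  Templates can optionally carry
a per-voxel age regression (offset + slope * age, ordinary least
squares on the controls) so that a patient is scored against the value
predicted for their age rather than the cohort mean — a single-subject
recasting of a different-offset/different-slope group design.

Testing is one-sided (z above threshold) because all three feature
modalities encode pathology as increases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import FeatureMap
from .volumes import BinaryMask, Volume3D, require_same_grid

logger = logging.getLogger("fcdkit")

#: default suprathreshold cutoff; the evaluation stage uses 2.0 where it
#: reproduces DICE-style outputs.
DEFAULT_Z_THRESHOLD = 1.96

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class AgeModel:
    """Per-voxel OLS regression of feature value on age (years)."""

    offset: np.ndarray       # intercept map
    slope: np.ndarray        # per-year slope map
    residual_sd: np.ndarray  # residual SD map (n-2 denominator)
    age_min: float
    age_max: float


@dataclass
class NormativeTemplate:
    """Voxel-wise mean/SD maps over a control cohort."""

    mu: Volume3D
    sigma: Volume3D
    n: int
    modality: str
    age_model: AgeModel = None
    ages: list = None

    def __post_init__(self):
        require_same_grid([self.mu, self.sigma], "template maps")
        if self.n < 2:
            raise ValueError("a normative template needs at least 2 controls")
        if self.sigma.data.min() < 0:
            raise ValueError("negative sigma in template")


@dataclass
class ZMap:
    """Voxel-wise deviation map of one patient against a template."""

    z: Volume3D
    modality: str
    sigma_floor: float


@dataclass
class ClusterRecord:
    id: int
    n_voxels: int
    volume_mm3: float
    peak_z: float
    peak_voxel: tuple


@dataclass
class ClusterSet:
    """Labeled connected components of a thresholded z-map."""

    label_map: np.ndarray          # 0 = background, clusters 1..K by peak z desc
    clusters: list                 # list[ClusterRecord]
    threshold: float
    connectivity: int
    spacing: tuple

    def __len__(self):
        return len(self.clusters)

    @property
    def total_mask(self) -> np.ndarray:
        return self.label_map > 0

    def cluster_mask(self, cluster_id: int) -> np.ndarray:
        return self.label_map == cluster_id

    def to_rows(self) -> list:
        """TSV-ready rows: id, n_voxels, volume_mm3, peak_z, x, y, z."""
        return [
            {"id": c.id, "n_voxels": c.n_voxels, "volume_mm3": c.volume_mm3,
             "peak_z": c.peak_z, "x": c.peak_voxel[0], "y": c.peak_voxel[1],
             "z": c.peak_voxel[2]}
            for c in self.clusters
        ]


# ---------------------------------------------------------------------------
# Template construction

def build_template(maps, ages=None) -> NormativeTemplate:
    """Voxel-wise mean and sample SD over >= 2 same-modality control maps.

    With ``ages``, a per-voxel OLS age regression (offset + slope) is
    fitted in addition; its residual SD uses an n-2 denominator and
    therefore needs n >= 3 controls.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 control maps to build a template")
    modalities = {m.modality for m in maps}
    if len(modalities) != 1:
        raise ValueError(f"mixed modalities in template cohort: {sorted(modalities)}")
    require_same_grid([m.map for m in maps], "control maps")
    stack = np.stack([m.map.data for m in maps])
    n = stack.shape[0]
    mu = stack.mean(axis=0)
    sigma = stack.std(axis=0, ddof=1)
    template = NormativeTemplate(
        mu=maps[0].map.with_data(mu), sigma=maps[0].map.with_data(sigma),
        n=n, modality=modalities.pop())
    if ages is not None:
        ages = np.asarray(ages, float)
        if ages.shape != (n,):
            raise ValueError(f"ages length {ages.size} != cohort size {n}")
        if n < 3:
            raise ValueError("age model needs at least 3 controls")
        a_c = ages - ages.mean()
        ss_age = float((a_c ** 2).sum())
        if ss_age == 0:
            raise ValueError("all control ages identical: age slope is unidentifiable")
        slope = np.tensordot(a_c, stack - mu, axes=(0, 0)) / ss_age
        offset = mu - slope * ages.mean()
        resid = stack - (offset + slope * ages[:, None, None, None])
        residual_sd = np.sqrt((resid ** 2).sum(axis=0) / (n - 2))
        template.age_model = AgeModel(offset=offset, slope=slope,
                                      residual_sd=residual_sd,
                                      age_min=float(ages.min()), age_max=float(ages.max()))
        template.ages = ages.tolist()
    return template


def default_sigma_floor(sigma: np.ndarray) -> float:
    """1% of the robust (median positive) sigma.

    Phantom templates can contain exactly-zero-SD voxels; the floor
    keeps z-maps finite without materially shrinking real deviations.
    """
    positive = sigma[sigma > 0]
    if positive.size == 0:
        return 1e-6
    return 0.01 * float(np.median(positive))


# ---------------------------------------------------------------------------
# Patient scoring

def zmap(patient: FeatureMap, template: NormativeTemplate,
         sigma_floor: float = None) -> ZMap:
    """Voxel-wise z = (patient - mu) / max(sigma, sigma_floor)."""
    _check_match(patient, template)
    if sigma_floor is None:
        sigma_floor = default_sigma_floor(template.sigma.data)
    denom = np.maximum(template.sigma.data, sigma_floor)
    z = (patient.map.data - template.mu.data) / denom
    return ZMap(z=patient.map.with_data(z), modality=patient.modality,
                sigma_floor=float(sigma_floor))


def age_adjusted_zmap(patient: FeatureMap, age: float, template: NormativeTemplate,
                      sigma_floor: float = None) -> ZMap:
    """Score a patient against the template value predicted for their age.

    z = (patient - (offset + slope * age)) / max(residual SD, floor).
    Warns when the patient's age falls more than 2 years outside the
    control age range (extrapolating a linear age model).
    """
    _check_match(patient, template)
    if template.age_model is None:
        raise ValueError("template has no age model (built without ages)")
    am = template.age_model
    if not (am.age_min - 2.0 <= age <= am.age_max + 2.0):
        warnings.warn(
            f"patient age {age:g} outside control range "
            f"[{am.age_min:g}, {am.age_max:g}] +/- 2 years; extrapolating",
            stacklevel=2)
    if sigma_floor is None:
        sigma_floor = default_sigma_floor(am.residual_sd)
    predicted = am.offset + am.slope * age
    denom = np.maximum(am.residual_sd, sigma_floor)
    z = (patient.map.data - predicted) / denom
    return ZMap(z=patient.map.with_data(z), modality=patient.modality,
                sigma_floor=float(sigma_floor))


def subtraction_map(patient: FeatureMap, template: NormativeTemplate) -> FeatureMap:
    """Plain voxel-wise difference patient - mu (no variance scaling)."""
    _check_match(patient, template)
    return FeatureMap(map=patient.map.with_data(patient.map.data - template.mu.data),
                      modality=patient.modality,
                      params=dict(patient.params, template_n=template.n))


def _check_match(patient: FeatureMap, template: NormativeTemplate) -> None:
    if patient.modality != template.modality:
        raise ValueError(
            f"modality mismatch: patient {patient.modality!r} vs template "
            f"{template.modality!r}")
    require_same_grid([patient.map, template.mu], "patient and template")


# ---------------------------------------------------------------------------
# Cluster extraction

def threshold_clusters(zm: ZMap, z_threshold: float = DEFAULT_Z_THRESHOLD,
                       connectivity: int = 26, min_cluster_mm3: float = 0.0,
                       exclusion: BinaryMask = None) -> ClusterSet:
    """Connected components of {z > threshold}, outside the exclusion mask.

    Components smaller than ``min_cluster_mm3`` are dropped; survivors
    are relabeled 1..K in order of decreasing peak z.
    """
    if not np.isfinite(z_threshold):
        raise ValueError("z threshold must be finite")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    supra = zm.z.data > z_threshold
    if exclusion is not None:
        require_same_grid([zm.z, exclusion], "z-map and exclusion mask")
        supra &= ~exclusion.as_bool()
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labeled, n_raw = ndimage.label(supra, structure=structure)
    voxel_volume = float(np.prod(zm.z.spacing))

    records = []
    for lab in range(1, n_raw + 1):
        where = labeled == lab
        n_vox = int(where.sum())
        vol = n_vox * voxel_volume
        if vol < min_cluster_mm3:
            continue
        zvals = np.where(where, zm.z.data, -np.inf)
        peak_flat = int(np.argmax(zvals))
        peak = np.unravel_index(peak_flat, zm.z.shape)
        records.append((lab, n_vox, vol, float(zm.z.data[peak]), tuple(int(i) for i in peak)))

    records.sort(key=lambda r: r[3], reverse=True)
    out_labels = np.zeros_like(labeled)
    clusters = []
    for new_id, (lab, n_vox, vol, peak_z, peak) in enumerate(records, start=1):
        out_labels[labeled == lab] = new_id
        clusters.append(ClusterRecord(id=new_id, n_voxels=n_vox, volume_mm3=vol,
                                      peak_z=peak_z, peak_voxel=peak))
    return ClusterSet(label_map=out_labels, clusters=clusters,
                      threshold=float(z_threshold), connectivity=connectivity,
                      spacing=zm.z.spacing)
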