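"""Per-subject feature maps: junction, extension, cortical thickness.

Three voxel-wise maps encode the imaging signatures of focal cortical
dysplasia type II:

* **junction** — blurring of the gray-white matter transition.  Voxels
  whose (mean-normalised) T1 intensity falls between
  ``MeanGM + 0.5 * S.D.GM`` and ``MeanWM - 0.5 * S.D.WM`` are marked 1;
  the binary image is smoothed with a 3D Gaussian kernel (6 mm FWHM by
  default), so the map reads as a local density of intermediate-
  intensity voxels.  Blurred transitions produce clusters of such
  voxels and hence high values.
* **extension** — abnormal gray-matter intensity/density, in particular
  GM extending into white matter.  Defined as the smoothed GM
  probability map restricted to a cortical mask.
* **thickness** — a voxel-based cortical-width surrogate, in mm: for
  every GM voxel, the Euclidean distance to the nearest WM voxel plus
  the distance to the nearest CSF/background voxel.  This dual distance
  transform on segmentation labels replaces surface reconstruction
  while preserving the quantity's meaning (local cortical width) for
  the normative z-scoring stage.

All three encode pathology as *increases*, which is why the normative
stage tests one-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import CSF, GM, WM, TissueSegmentation, TissueStats
from .volumes import BinaryMask, SmoothingSpec, Volume3D, require_same_grid, smooth_gaussian

logger = logging.getLogger("fcdkit")

MODALITIES = ("junction", "extension", "thickness")


@dataclass
class FeatureMap:
    """A per-subject scalar map tagged with its modality and parameters."""

    map: Volume3D
    modality: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")


@dataclass
class JunctionThresholds:
    """Intensity band bounding blurred GM-WM transition voxels."""

    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(
                f"degenerate GM-WM band: lower threshold {self.lower:g} >= "
                f"upper threshold {self.upper:g}")


def junction_thresholds(stats: TissueStats) -> JunctionThresholds:
    """Band limits: MeanGM + 0.5*S.D.GM (lower), MeanWM - 0.5*S.D.WM (upper)."""
    return JunctionThresholds(lower=stats.mean_gm + 0.5 * stats.sd_gm,
                              upper=stats.mean_wm - 0.5 * stats.sd_wm)


def junction_map(vol: Volume3D, stats: TissueStats, brain_mask: BinaryMask,
                 spec: SmoothingSpec = None) -> FeatureMap:
    """Smoothed binary image of intermediate-intensity voxels.

    ``vol`` must be on the same intensity scale as ``stats`` (in the
    standard pipeline both come from the mean-normalised T1).  Masking
    precedes smoothing, so out-of-mask voxels contribute nothing to the
    density.  Values lie in [0, 1].
    """
    if spec is None:
        spec = SmoothingSpec()
    require_same_grid([vol, brain_mask], "volume and brain mask")
    thr = junction_thresholds(stats)
    binary = ((vol.data >= thr.lower) & (vol.data <= thr.upper)
              & brain_mask.as_bool()).astype(float)
    smoothed = smooth_gaussian(vol.with_data(binary), spec)
    return FeatureMap(map=smoothed, modality="junction",
                      params={"lower": thr.lower, "upper": thr.upper,
                              "fwhm_mm": spec.fwhm_mm})


def extension_map(seg: TissueSegmentation, cortical_mask: BinaryMask,
                  spec: SmoothingSpec = None) -> FeatureMap:
    """Smoothed GM probability restricted to the cortical mask.

    The cortical mask excludes non-cortical gray matter (basal ganglia,
    brainstem, cerebellum) on real data; phantoms provide their own
    ground-truth mask.  Values lie in [0, 1].
    """
    if spec is None:
        spec = SmoothingSpec()
    require_same_grid([seg.prob_gm, cortical_mask], "GM probability and cortical mask")
    if cortical_mask.n_voxels == 0:
        raise ValueError("empty cortical mask")
    gm = seg.prob_gm.data * cortical_mask.as_bool()
    smoothed = smooth_gaussian(seg.prob_gm.with_data(gm), spec)
    return FeatureMap(map=smoothed, modality="extension",
                      params={"fwhm_mm": spec.fwhm_mm})


def thickness_map(seg: TissueSegmentation) -> FeatureMap:
    """Cortical-width surrogate from a dual Euclidean distance transform.

    thickness(v) for a GM voxel v = distance to the nearest WM voxel +
    distance to the nearest CSF/background voxel, in mm (voxel spacing
    honoured); 0 outside GM.  On a flat slab this reports the slab
    width (plus ~1 voxel of rasterisation bias, since distances are
    measured between voxel centers).
    """
    labels = seg.labels.data
    spacing = seg.labels.spacing
    gm = labels == GM
    wm = labels == WM
    outer = ~(gm | wm)  # CSF or background
    if not gm.any():
        warnings.warn("no GM voxels: thickness map is identically zero", stacklevel=2)
        return FeatureMap(map=seg.labels.with_data(np.zeros(labels.shape)),
                          modality="thickness", params={})
    if not wm.any():
        raise ValueError("missing WM class: cannot measure inner cortical boundary")
    if not outer.any():
        raise ValueError("missing CSF/background class: cannot measure outer cortical boundary")
    # distance_transform_edt measures distance to the nearest zero voxel
    d_wm = ndimage.distance_transform_edt(~wm, sampling=spacing)
    d_outer = ndimage.distance_transform_edt(~outer, sampling=spacing)
    thick = np.where(gm, d_wm + d_outer, 0.0)
    return FeatureMap(map=seg.labels.with_data(thick), modality="thickness", params={})
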