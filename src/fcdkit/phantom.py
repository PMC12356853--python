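"""Synthetic T1 head phantoms with ground-truth masks and lesions.

The phantom emulates the data model the detection pipelines operate on:
a nested ellipsoidal head — background, a CSF shell, a cortical
gray-matter ribbon of controlled thickness, and a white-matter core —
with T1-like intensity ordering CSF < GM < WM and additive Gaussian
noise.  Region boundaries are placed at exact millimetre depths below
the brain surface (via a Euclidean distance transform), so ribbon
thickness is controlled in mm regardless of the ellipsoid's shape.

Lesions model the two FCD type II signatures the detectors target:

* ``junction_blur`` replaces the sharp GM->WM intensity step inside a
  sphere by a linear ramp of configurable width across the boundary —
  the classic blurred gray-white junction;
* ``thickening`` locally extends the GM ribbon into the white matter by
  a configurable depth — focal cortical thickening.

Resection cavities are carved by setting a sphere to CSF intensity.
Everything is seeded and deterministic; a cohort generator produces
control groups with multiplicative geometric jitter and an optional
linear age-thickness trend for age-model recovery studies.

Deliberately not modelled: gyrification, Rician noise, bias fields,
partial-volume point spread, and the transmantle sign — none of which
the thresholding/z-scoring logic under test consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .segmentation import BACKGROUND, CSF, GM, WM, TissueSegmentation, tissue_stats
from .volumes import BinaryMask, Volume3D

logger = logging.getLogger("fcdkit")

LESION_TYPES = ("junction_blur", "thickening", "both")


@dataclass
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic head.

    Defaults give a 64 mm^3 head at 1 mm isotropic spacing with a 3 mm
    CSF shell, a 4 mm cortical ribbon, tissue means 30/80/130
    (CSF/GM/WM, arbitrary T1-like units) and noise SD 2 — about 1.5% of
    the WM mean, a clean but not noiseless regime.
    """

    shape: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)
    semi_axes_mm: tuple = (26.0, 22.0, 22.0)
    csf_thickness_mm: float = 3.0
    ribbon_thickness_mm: float = 4.0
    mean_csf: float = 30.0
    mean_gm: float = 80.0
    mean_wm: float = 130.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (self.mean_csf < self.mean_gm < self.mean_wm):
            raise ValueError("tissue means must be ordered CSF < GM < WM")
        if self.ribbon_thickness_mm >= min(self.semi_axes_mm):
            raise ValueError("cortical ribbon thicker than the brain")
        if self.csf_thickness_mm + self.ribbon_thickness_mm >= min(self.semi_axes_mm):
            raise ValueError("CSF shell plus ribbon thicker than the brain")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    @property
    def wm_depth_mm(self) -> float:
        """Depth below the brain surface at which white matter starts."""
        return self.csf_thickness_mm + self.ribbon_thickness_mm


@dataclass
class LesionSpec:
    """A spherical FCD-like lesion intersecting the cortical ribbon."""

    center_mm: tuple            # world coordinates
    radius_mm: float
    kind: str = "junction_blur"
    blur_ramp_mm: float = 4.0
    thickening_mm: float = 3.0

    def __post_init__(self):
        if self.radius_mm < 0:
            raise ValueError("lesion radius must be non-negative")
        if self.kind not in LESION_TYPES:
            raise ValueError(f"lesion type must be one of {LESION_TYPES}")


@dataclass
class HeadPhantom:
    """A generated head: T1, ground-truth tissue maps, masks, geometry."""

    t1: Volume3D
    labels: TissueSegmentation   # ground-truth one-hot segmentation
    brain_mask: BinaryMask
    cortical_mask: BinaryMask
    spec: PhantomSpec
    clean: np.ndarray = None     # noiseless intensity field
    noise: np.ndarray = None     # the added noise realisation
    depth_mm: np.ndarray = None  # depth below brain surface, mm (0 outside)

    def gm_wm_boundary_point(self, direction=(1.0, 0.0, 0.0)) -> tuple:
        """World coordinates of a point on the GM/WM interface.

        Walks from the head center along ``direction`` to the depth at
        which white matter starts; convenient for placing lesions.
        """
        d = np.asarray(direction, float)
        d /= np.linalg.norm(d)
        center = _center_mm(self.spec)
        # bisect on the depth map along the ray
        lo, hi = 0.0, float(max(self.spec.semi_axes_mm))
        target = self.spec.wm_depth_mm
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            p = center + mid * d
            idx = tuple(np.clip(np.rint(p / self.spec.spacing).astype(int), 0,
                                np.array(self.spec.shape) - 1))
            if self.depth_mm[idx] > target:
                lo = mid
            else:
                hi = mid
        return tuple(center + 0.5 * (lo + hi) * d)


def _center_mm(spec: PhantomSpec) -> np.ndarray:
    return (np.array(spec.shape, float) - 1.0) / 2.0 * np.array(spec.spacing, float)


def _world_grids(spec: PhantomSpec):
    return np.meshgrid(*[np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)],
                       indexing="ij")


def _labels_from_depth(depth: np.ndarray, inside: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    labels = np.full(spec.shape, BACKGROUND, dtype=int)
    labels[inside & (depth < spec.csf_thickness_mm)] = CSF
    labels[inside & (depth >= spec.csf_thickness_mm) & (depth < spec.wm_depth_mm)] = GM
    labels[inside & (depth >= spec.wm_depth_mm)] = WM
    return labels


def _intensity_from_labels(labels: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    lut = np.array([0.0, spec.mean_csf, spec.mean_gm, spec.mean_wm])
    return lut[labels]


def _segmentation_from_labels(labels: np.ndarray, t1: Volume3D,
                              with_stats: bool = True) -> TissueSegmentation:
    seg = TissueSegmentation(
        labels=t1.with_data(labels),
        prob_csf=t1.with_data((labels == CSF).astype(float)),
        prob_gm=t1.with_data((labels == GM).astype(float)),
        prob_wm=t1.with_data((labels == WM).astype(float)),
    )
    if with_stats:
        seg.stats = tissue_stats(t1, seg)
    return seg


def make_head_phantom(spec: PhantomSpec = None) -> HeadPhantom:
    """Rasterise one head phantom; deterministic per seed."""
    if spec is None:
        spec = PhantomSpec()
    grids = _world_grids(spec)
    center = _center_mm(spec)
    rho2 = sum(((g - c) / a) ** 2
               for g, c, a in zip(grids, center, spec.semi_axes_mm))
    inside = rho2 <= 1.0
    depth = ndimage.distance_transform_edt(inside, sampling=spec.spacing)
    labels = _labels_from_depth(depth, inside, spec)

    clean = _intensity_from_labels(labels, spec)
    rng = np.random.default_rng(spec.seed)
    noise = np.zeros(spec.shape)
    noise[inside] = rng.normal(0.0, spec.noise_sd, int(inside.sum())) if spec.noise_sd > 0 else 0.0

    affine = np.diag(list(spec.spacing) + [1.0])
    t1 = Volume3D(data=clean + noise, affine=affine, space_tag="phantom")
    seg = _segmentation_from_labels(labels, t1)
    brain_mask = BinaryMask(data=inside.astype(np.uint8), affine=affine)
    # the phantom models no non-cortical structures (basal ganglia,
    # brainstem, cerebellum), so its "cortical" mask is the brain itself
    cortical_mask = BinaryMask(data=inside.astype(np.uint8), affine=affine)
    return HeadPhantom(t1=t1, labels=seg, brain_mask=brain_mask,
                       cortical_mask=cortical_mask, spec=spec, clean=clean,
                       noise=noise, depth_mm=depth)


def insert_fcd_lesion(phantom: HeadPhantom, lesion: LesionSpec):
    """Plant an FCD-like lesion; returns (lesioned phantom, lesion mask).

    Voxels outside the lesion are bit-identical to the input phantom
    (the same noise realisation is re-applied to the modified clean
    field).  The lesion mask marks every modified voxel.
    """
    spec = phantom.spec
    grids = _world_grids(spec)
    r2 = sum((g - c) ** 2 for g, c in zip(grids, lesion.center_mm))
    sphere = r2 <= lesion.radius_mm ** 2

    depth = phantom.depth_mm
    b = spec.wm_depth_mm
    labels = phantom.labels.labels.data.astype(int).copy()
    clean = phantom.clean.copy()

    if lesion.radius_mm > 0:
        ribbon = labels == GM
        if not (sphere & ribbon).any():
            raise ValueError("lesion sphere does not intersect the cortical ribbon")

    if lesion.kind in ("thickening", "both") and lesion.radius_mm > 0:
        extend = sphere & (labels == WM) & (depth < b + lesion.thickening_mm)
        labels[extend] = GM
        clean[extend] = spec.mean_gm

    if lesion.kind in ("junction_blur", "both") and lesion.radius_mm > 0:
        # boundary depth of the (possibly thickened) ribbon inside the sphere
        b_eff = b + (lesion.thickening_mm if lesion.kind == "both" else 0.0)
        w = lesion.blur_ramp_mm
        band = sphere & (np.abs(depth - b_eff) <= w / 2.0) & (labels != BACKGROUND) \
            & (labels != CSF)
        frac = np.clip((depth - (b_eff - w / 2.0)) / w, 0.0, 1.0)
        ramp = spec.mean_gm + (spec.mean_wm - spec.mean_gm) * frac
        clean[band] = ramp[band]

    changed = np.abs(clean - phantom.clean) > 1e-9
    changed |= labels != phantom.labels.labels.data
    lesion_mask = BinaryMask(data=changed.astype(np.uint8), affine=phantom.t1.affine)

    t1 = phantom.t1.with_data(clean + phantom.noise)
    seg = _segmentation_from_labels(labels, t1)
    gm_or = phantom.cortical_mask.as_bool() | (labels == GM)
    lesioned = HeadPhantom(t1=t1, labels=seg, brain_mask=phantom.brain_mask,
                           cortical_mask=phantom.cortical_mask.with_data(
                               gm_or.astype(np.uint8)),
                           spec=spec, clean=clean, noise=phantom.noise,
                           depth_mm=phantom.depth_mm)
    logger.info("inserted %s lesion r=%.1f mm: %d voxels modified",
                lesion.kind, lesion.radius_mm, lesion_mask.n_voxels)
    return lesioned, lesion_mask


def carve_resection(phantom: HeadPhantom, center_mm, radius_mm: float,
                    seed: int = None) -> Volume3D:
    """Post-operative T1: a sphere set to CSF intensity (plus noise).

    The sphere must lie entirely inside the brain; voxels outside it
    are bit-identical to the pre-operative volume.
    """
    spec = phantom.spec
    grids = _world_grids(spec)
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    sphere = r2 <= radius_mm ** 2
    if radius_mm > 0:
        if not sphere.any():
            raise ValueError("resection sphere contains no voxels")
        if (sphere & ~phantom.brain_mask.as_bool()).any():
            raise ValueError("resection sphere extends outside the brain")
    post = phantom.t1.data.copy()
    n = int(sphere.sum())
    if n:
        rng = np.random.default_rng(spec.seed + 7919 if seed is None else seed)
        post[sphere] = spec.mean_csf + (rng.normal(0.0, spec.noise_sd, n)
                                        if spec.noise_sd > 0 else 0.0)
    return phantom.t1.with_data(post)


def make_cohort(n: int, spec: PhantomSpec = None, jitter: float = 0.02,
                ages=None, age_thickness_slope: float = 0.0,
                seed: int = None) -> list:
    """Generate a control cohort of seeded phantoms.

    Per-subject ellipsoid semi-axes and ribbon thickness are jittered
    multiplicatively (fraction ``jitter`` of their value, Gaussian,
    clipped at +/- 3 jitter).  With ``ages``, ribbon thickness follows
    base + slope * age before jitter, enabling recovery of a planted
    age-thickness trend from the template's age model.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if spec is None:
        spec = PhantomSpec()
    if ages is not None and len(ages) != n:
        raise ValueError(f"ages length {len(ages)} != cohort size {n}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cohort = []
    for i in range(n):
        child_seed = int(rng.integers(0, 2**31 - 1))
        g = np.clip(rng.standard_normal(4), -3.0, 3.0)
        axes = tuple(a * (1.0 + jitter * g[k]) for k, a in enumerate(spec.semi_axes_mm))
        thickness = spec.ribbon_thickness_mm
        if ages is not None:
            thickness = thickness + age_thickness_slope * float(ages[i])
        thickness *= 1.0 + jitter * g[3]
        subject_spec = replace(spec, semi_axes_mm=axes,
                               ribbon_thickness_mm=thickness, seed=child_seed)
        cohort.append(make_head_phantom(subject_spec))
    return cohort
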