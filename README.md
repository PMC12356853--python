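# fcdkit

Voxel-based detection of **focal cortical dysplasia type II (FCD II)** on
T1-weighted MRI, with the evaluation machinery used to validate such
detectors against surgical ground truth.

FCD II is the most common cause of drug-resistant focal epilepsy in
children. Its imaging signatures — blurring of the gray–white matter
junction and focal cortical thickening — are subtle and frequently missed
on visual reading, so morphometric post-processing is used to flag
candidate regions for the surgical team. This package implements that
post-processing stack end-to-end for researchers studying automated FCD
detection: the per-subject feature maps, normative z-scoring against
healthy-control templates, candidate-cluster extraction, automatic
post-resection-cavity segmentation, and the DICE / percent-overlay /
ROC evaluation layer. Because clinical MRI in this setting is restricted,
the package ships a seeded synthetic head-phantom generator that provides
ground-truth lesions, cohorts and resection cavities for every test.

## Method

For each subject, the T1 volume is mean-normalised inside the brain mask
and segmented into CSF/GM/WM by a three-component Gaussian-mixture EM fit
(deterministic quantile initialisation). Three feature maps follow:

* **Junction** — voxels with intensity in the band
  `[mean_GM + 0.5·SD_GM, mean_WM − 0.5·SD_WM]` form a binary image that is
  smoothed with a 3D Gaussian kernel (FWHM 6 mm); high values mark local
  accumulations of intermediate gray–white intensities, i.e. blurred
  junctions.
* **Extension** — the smoothed GM probability map restricted to a cortical
  mask; highlights abnormal GM density, e.g. GM extending into WM.
* **Thickness** — a voxel-based cortical-width surrogate: for each GM voxel,
  the Euclidean distance to the nearest WM voxel plus the distance to the
  nearest CSF/background voxel (mm).

A normative template holds the voxel-wise mean μ and sample SD σ of a
feature over a control cohort (optionally with a per-voxel age regression).
A patient map *x* is scored as

    z = (x − μ) / max(σ, σ_floor)

and thresholded one-sided (default z > 1.96, the two-sided p = 0.05
Gaussian cutoff) to yield candidate clusters ranked by peak z.

The post-resection cavity (PRC) — the reference mask for evaluation — is
detected from a co-registered pre/post-operative pair: scale both by the
pre-operative in-brain mean, smooth (6 mm FWHM), subtract post from pre,
threshold the positive difference, and keep the selected connected
component. Agreement metrics are DICE = 2|A∩B|/(|A|+|B|), percent overlay
= 100·|A∩B|/|B| (fraction of the reference covered), and a voxel-level
ROC: TPR is the detected fraction of the reference, FPR the detected
fraction of the brain excluding it, AUC by trapezoid.

## Worked example

```python
import fcdkit as fk

# overlap bookkeeping on the bundled reference cohort
row = fk.datasets.surgical_series().loc[19]
detected, reference = fk.datasets.synthetic_mask_pair(
    int(row.prr_mm3), int(row.prc_mm3), int(row.overlap_mm3))
rep = fk.overlap_report(detected, reference)
print(f"subject 19: overlay {rep.percent_overlay}% of the cavity, DICE {rep.dice:.3f}")

# end-to-end detection on a synthetic cohort
controls = fk.make_cohort(20, fk.PhantomSpec(noise_sd=2.6, seed=11), jitter=0.02)
template = fk.build_cohort_template(controls, "junction")

patient = fk.make_head_phantom(fk.PhantomSpec(noise_sd=2.6, seed=99))
lesion_center = patient.gm_wm_boundary_point()
patient, lesion_mask = fk.insert_fcd_lesion(
    patient, fk.LesionSpec(center_mm=lesion_center, radius_mm=8.0,
                           kind="junction_blur", blur_ramp_mm=4.0))

result = fk.run_detection(patient.t1, patient.brain_mask, patient.cortical_mask,
                          template, fk.RunConfig(modality="junction"))
top = result.clusters.clusters[0]
auc = fk.roc_curve(result.zmap.z, lesion_mask, patient.brain_mask).auc
```

Output:

```
subject 19: overlay 34.1% of the cavity, DICE 0.450
1 cluster(s); top cluster: 1976 mm^3, peak z = 23.0, overlaps lesion: True
voxel-level AUC of the junction z-map against the lesion: 0.999
```

Subject 19's radiological ROI (1593 mm³) covers 34.1 % of the 3096 mm³
resection cavity — the largest overlay in the bundled series. On the
synthetic patient, the junction pipeline returns a single suprathreshold
cluster sitting on the planted blurred-junction lesion, with a z-map that
separates lesion from background almost perfectly (AUC 0.999).

A command-line interface mirrors the library
(`fcdkit simulate | segment | features | build-template | detect |
detect-prc | evaluate`); see `fcdkit --help`.

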