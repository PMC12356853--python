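# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `fcdkit`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and grids

All images are 3D scalar grids (`Volume3D`) or 0/1 masks (`BinaryMask`)
with per-axis voxel spacing in mm and a 4×4 voxel-to-world affine;
NIfTI-1 is the only on-disk format (masks as uint8, maps as float32).
Every operation requires its inputs on one common grid and checks this;
nothing is resampled silently. Registration is out of scope: real data
must be co-registered upstream, and phantoms are generated aligned. A
center-of-mass integer-voxel translation is offered purely as a
convenience for removing whole-voxel offsets. NaN/Inf voxels are rejected
at construction and at read time (with the affected voxel count), rather
than propagated.

## Smoothing

The Gaussian kernel is parameterised by FWHM in mm, the convention of the
voxel-based-morphometry literature; σ = FWHM / (2√(2 ln 2)), so the
default 6 mm FWHM gives σ ≈ 2.548 mm. Whether a stated "6 mm" kernel
means FWHM or σ is a convention choice, so the width is a configuration
knob (`SmoothingSpec`), not a constant. Smoothing is separable, honours
anisotropic spacing (σ in voxels = σ_mm / spacing per axis), and uses a
renormalised boundary: the zero-padded convolution is divided by the
smoothed indicator of the grid. This keeps constant inputs exactly
constant, avoids rim artifacts in junction maps, and coincides with plain
convolution for interior-supported signals (the property the tests
exploit: interior impulses reproduce the closed-form discrete kernel to
1e-6). Kernel support is truncated at 4σ.

## Tissue segmentation

A three-component univariate Gaussian mixture is fitted to in-mask
intensities by EM. Initialisation is deterministic — component means at
the 25th/50th/75th intensity percentiles, equal weights, equal variances —
so identical inputs give bit-identical outputs; the `seed` argument
exists only for interface symmetry. Convergence: relative log-likelihood
change < 1e-8 or 500 iterations (non-convergence raises, reporting the
final log-likelihood delta). The log-likelihood is asserted
non-decreasing every iteration. Components map to CSF/GM/WM in
increasing order of fitted mean (the T1 ordering); posterior
responsibilities are the probability maps and argmax gives labels.
Labels are invariant under affine intensity rescaling.

This is deliberately a self-contained replacement for atlas-prior
unified segmentation: no spatial priors, no bias-field model, no skull
stripping. It is adequate for bias-free, brain-masked inputs and for
phantom-scale validation; externally produced probability maps can be
injected via `accept_external_probmaps` for real data.

Tissue statistics (MeanGM, SD_GM, MeanWM, SD_WM) use voxels with tissue
probability > 0.5 (default), which excludes partial-volume voxels that
would pull the two means together and squeeze the junction band; SD is
the sample standard deviation (n−1).

## Feature maps

* **Junction**: binary image of voxels with intensity in
  [MeanGM + 0.5·SD_GM, MeanWM − 0.5·SD_WM] (inclusive) inside the brain
  mask, then Gaussian-smoothed. Masking precedes smoothing so out-of-mask
  voxels contribute nothing (the order is configurable in principle but
  mask-then-smooth is the implementation default). The junction image is
  evaluated on the mean-normalised T1 with statistics computed on the
  same volume, so thresholds and voxel values share one scale.
* **Extension**: smoothed GM probability restricted to the cortical mask.
  GM probability (not raw T1) is the self-contained analog of
  gray-matter density; the cortical mask excludes non-cortical gray
  matter (basal ganglia, brainstem, cerebellum) on real data and is an
  input NIfTI mask there.
* **Thickness**: dual distance transform on labels — for each GM voxel,
  Euclidean distance to the nearest WM voxel plus distance to the nearest
  CSF/background voxel. This surrogate replaces surface reconstruction
  while keeping the quantity's meaning (local cortical width in mm). It
  carries a rasterisation bias of about one voxel (distances are between
  voxel centers): a 6-voxel slab reads ~7 mm. The bias is common to
  patients and controls, so it cancels in z-scores; absolute thickness
  values should not be read as calibrated cortical thickness.

All three modalities encode pathology as increases, which is why
z-testing is one-sided.

## Normative scoring

Templates store the voxel-wise mean and sample SD (n−1) over ≥ 2
same-modality control maps. With ages, a per-voxel ordinary
least-squares regression of value on age (offset + slope) is fitted;
residual SD uses an n−2 denominator (n ≥ 3 required). A patient is
scored as z = (x − μ)/max(σ, σ_floor); with an age model, μ is replaced
by the age-predicted value and σ by the residual SD. This realises a
different-offset/different-slope design at the single-subject level:
the controls determine the age trend, the patient is scored as a
deviation from it; no two-group GLM is fitted (there is no patient
group at n = 1). Scoring a patient more than 2 years outside the
control age range warns (linear extrapolation).

σ_floor defaults to 1 % of the median positive σ: phantom templates can
contain exactly-zero-SD voxels (identical geometry across controls), and
the floor keeps z finite without shrinking real deviations. The default
z threshold is 1.96 (two-sided p = 0.05 Gaussian cutoff, computed not
hard-coded); evaluation against resection masks conventionally uses
z > 2, so both appear in configs. Cluster extraction uses 26-neighbour
connectivity by default and no minimum cluster volume; clusters are
relabeled 1..K by decreasing peak z.

## Post-resection cavity detection

Both volumes are divided by the **pre-operative** in-brain mean. A single
shared constant (rather than each volume's own mean) is used because the
cavity itself deflates the post-operative mean — removing several cm³ of
bright tissue shifts it by ~10 % on phantom scale — and per-volume
normalisation would tint the entire difference map by that shift. The
per-volume option (`normalization="each"`) remains available for data
with genuine between-session gain differences.

After smoothing (6 mm FWHM) and subtraction (pre − post), voxels above a
threshold form candidates and one connected component is kept: the
largest by default, or the one nearest a user seed point. The default
threshold adapts to the data: 0.375 × the peak positive difference. The
rationale is closed-form: the smoothed indicator of a ball of radius R
attains, at its true boundary, the fraction
0.5 − (σ/R)·φ(0) ≈ 0.33–0.42 of its peak for R between ~2σ and ~5σ
(σ = 2.55 mm), so a cut at 37.5 % of peak recovers the boundary
approximately unbiased across cavity sizes of 6–12 mm radius, whereas a
low absolute cut (e.g. 0.05 on the normalised scale) sits ~1.6σ down the
smoothed skirt and inflates the recovered volume severalfold. An
absolute threshold can still be passed; recovered volume is monotone
non-increasing in it. With the adaptive threshold, a no-change pair
yields "no cavity detected"; on noisy no-cavity data the adaptive rule
would latch onto the largest noise blob, so an absolute threshold is the
right choice when a cavity may be absent.

## Evaluation

DICE, percent overlay and the cluster-overlap table follow the standard
definitions (percent overlay is reported to one decimal; a cluster counts
as overlapping the reference if at least one voxel is inside it). Empty
references make overlay/DICE undefined and are reported as missing (NaN)
with a warning — never as zero. The voxel-level ROC sweeps 200 (default)
evenly spaced thresholds from the in-brain maximum to minimum, uses a
strictly-greater detection predicate, appends the (0,0) and (1,1)
endpoints and integrates by trapezoid; at 10⁴ thresholds it agrees with
the rank-based (Mann–Whitney) AUC to well under 0.005 on 32³ instances.
A constant score map returns a degenerate chance-level curve (AUC 0.5)
with a warning. Paired comparisons use the classical paired t-test
(zero-variance differences reported as t = 0, p = 1 with a warning);
multiplicity adjustment is Holm–Šídák step-down
(adjusted_(i) = 1 − (1 − p_(i))^(m−i+1) with a running maximum), delegated
to statsmodels and cross-checked against the closed form in tests. The
omnibus repeated-measures ANOVA is not reimplemented.

The bundled reference cohort (`fcdkit.datasets.surgical_series`) carries
the PRR/PRC/overlap volumes of a 23-subject pediatric FCD II surgical
series used for worked examples. Subject 2's row is internally
inconsistent in the source table; its cavity volume is reconstructed
from the cohort mean, the row is flagged `consistent=False`, and it is
excluded from worked examples.

## Phantoms

The generator rasterises a nested ellipsoidal head — background, 3 mm CSF
shell, cortical GM ribbon (default 4 mm), WM core — with boundaries placed
at exact mm depths below the brain surface via a distance transform, so
ribbon thickness is controlled in mm regardless of ellipsoid shape.
Defaults: 64³ grid at 1 mm isotropic, semi-axes (26, 22, 22) mm, tissue
means 30/80/130 (CSF/GM/WM), additive Gaussian noise SD 2 (~1.5 % of the
WM mean; end-to-end detection tests use 2 % of WM). Lesions:
`junction_blur` replaces the GM→WM step inside a sphere with a linear
ramp (default width 4 mm); `thickening` extends the ribbon into WM
(default 3 mm). Cavities are carved to CSF intensity. All outputs are
seeded and deterministic; voxels outside a lesion or cavity are
bit-identical to the unmodified phantom. Cohorts jitter semi-axes and
ribbon thickness multiplicatively (default 2 %, a modest anatomical
variability) and can plant a linear age–thickness trend.

What the phantom does **not** model: gyrification, Rician noise, bias
fields, partial-volume point spread, the transmantle sign, and
non-cortical gray-matter structures (hence its cortical mask equals the
brain mask). Passing tests therefore demonstrate the correctness of the
thresholding/z-scoring logic and the detectability of planted
signatures under controlled conditions — not clinical sensitivity or
specificity on real MRI, where segmentation quality, registration and
anatomical variability dominate.

Two phantom-specific calibration facts matter for interpreting tests:

* A 6-mm kernel makes the z-field spatially correlated on the kernel
  scale, so lesion-free controls show suprathreshold noise clusters
  approaching the kernel resel volume (~(√2·FWHM)³ ≈ 600 mm³) even when
  the voxel-wise false-positive rate is exactly nominal. The null-subject
  test therefore bounds cluster size by the resel volume and checks the
  suprathreshold fraction, rather than expecting near-voxel-scale
  clusters. Fragmented near-threshold clusters in controls are an
  expected property of kernel-smoothed maps, which is also why full
  z-maps, not only thresholded clusters, should be read in practice.
* With zero geometric jitter the axis-aligned ellipsoid on a regular grid
  makes rasterised thickness change in large synchronized steps across a
  cohort, which attenuates per-voxel age-slope estimates; the default 2 %
  jitter dithers the staircase and the median interior-ribbon slope then
  recovers a planted trend. Slope-recovery tests use the generator
  defaults.

## Problem sizes

The test suite and the acceptance script run on 64³ phantoms with
cohorts of 20–30 controls and 32³ noise fields for calibration and ROC
oracles — sizes at which every stage's behaviour (EM convergence,
smoothing, cluster statistics) is already in its asymptotic regime while
a full run stays within a few minutes on one CPU.

## Known limitations

* The GMM segmenter has no spatial or anatomical priors; on real MRI with
  bias fields it will misestimate tissue statistics unless bias is
  corrected upstream or external probability maps are supplied.
* The thickness surrogate is a voxel-grid quantity; it is not comparable
  to surface-based cortical thickness in absolute terms.
* The cavity detector assumes the cavity is the dominant intensity-loss
  region; post-operative brain shift and non-cavity signal changes are
  not modelled.
* The adaptive cavity threshold presumes a cavity exists; use an absolute
  threshold for screening data where none may be present.
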