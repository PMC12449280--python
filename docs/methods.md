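# Methods

## The preprocessing model

All preprocessing operates on one 3-D volume at a time, treating its
voxel values as a multiset X.

* **Clipping.** Intensities are clamped to `[clip_lo, clip_hi]`,
  default 0–3000. MR intensities are scanner-arbitrary; the upper bound
  caps rare hyperintense outliers so that the subsequent inversion is
  not dominated by them. The `unprocessed` variant receives no clipping
  (by definition it receives nothing at all).
* **Plain inversion.** `x -> max(X) - x + min(X)`. This is an
  involution, preserves the value range exactly, and reverses intensity
  order, mapping the T1w brightness ordering (fat bright, bone dark)
  onto a CT-like one (dense tissue bright).
* **Background zeroing (`inverted_black`).** After clipping, let `t` be
  the p-th percentile (default p = 1, linear interpolation over all
  voxels) of the clipped, pre-inversion intensities. Voxels with
  `x <= t` are set to exactly 0; all others are inverted as above. The
  threshold is inclusive: on a constant volume every voxel is at the
  percentile value and the output is identically zero.

Why a *value* threshold rather than a fixed 1%-of-voxels quota:
background air in magnitude MR images forms a large (often far more
than 1% of voxels) near-constant plateau at the very bottom of the
histogram. The first-percentile *value* lands on that plateau, so the
inclusive comparison `x <= t` blacks out essentially all of the
plateau, which is the stated purpose of the step — without it, plain
inversion turns the air surrounding the patient into the brightest
structure in the image. Tie handling at exactly `t` and the percentile
interpolation rule are implementation choices documented here; both are
configurable only through p.

The percentile is computed on the clipped pre-inversion intensities
(the rule is expressed in terms of the original x), and the zeroing is
applied in the same pass as the inversion.

## Volume handling

NIfTI I/O goes through nibabel. Volumes are reoriented to the
closest-to-RAS axis order on load so that sided structures are well
defined; under the canonical affine the first array axis increases
toward the patient's right, so patient-left anatomy sits at low
first-axis indices. Resampling to an isotropic grid (default 1 mm, the
working resolution of the pipeline) uses `scipy.ndimage.map_coordinates`
with voxel-center alignment at index 0 — linear interpolation for
intensity volumes, nearest-neighbor for label maps so no fractional or
novel class ids can appear. Output spacing is exactly the requested
value; the physical extent is preserved to within one voxel per axis,
and label volumes are conserved to within 5% for structures of at least
100 voxels (verified by test). SimpleITK would be the other natural
choice here; the scipy route was preferred because all phantom affines
are axis-aligned and the coordinate arithmetic stays transparent and
easily testable.

## The window backend

The desk-scale segmenter is a table of intensity windows, one row per
class: `[lo, hi]` intensity bounds, a minimum 26-connected component
volume in mm³, an optional left/right-of-midline constraint (midline =
the grid's middle sagittal plane), and an integer priority. Windows are
processed in descending priority; voxels claimed by a higher-priority
window are not reassigned. The component filter runs on the raw
candidate mask of each window, so lowering the threshold can only add
voxels (monotonicity, tested). The backend is deterministic by
construction.

Because the default table encodes CT intensity priors — air very dark,
lung dark, fat moderately dark, soft organs in a graded mid-range,
contrast-filled aorta brighter, bone very bright — it behaves like a
frozen CT-trained model: accurate on CT-like inputs, useless on raw
T1w-like inputs, and accurate again on inverted T1w-like inputs. Real
models (TotalSegmentator, an nnU-Net lesion model) are reachable through
the external-command adapter, which never resamples or renames
anything silently; multi-file outputs are merged only through an
explicit name → id map.

## The phantom

Each synthetic subject is built from ellipsoids and cylinders placed at
plausible relative positions inside an elliptical body cylinder:
paired lungs (superior), liver (patient right), spleen (left),
gallbladder, paired kidneys (posterior), a midline aorta, a posterior
bone column, paraspinal muscle cylinders, fat filling the rest of the
body, and a spherical renal lesion in the requested kidney. Geometry is
specified in fractional coordinates of the physical extent (any grid
shape/spacing works) and jittered ±10% per seed. The lesion radius is
found by bisection so the realized voxel volume matches the requested
volume to within 10%; an unfittable request raises an error rather than
silently clipping.

Per-tissue mean intensities live in one editable JSON table
(`data/phantom_tissues.json`). The orderings encode the transfer
mechanism:

* CT-like: air (−1000) ≪ lung < fat < gallbladder < muscle < liver <
  spleen < kidney < lesion < aorta < bone (HU-like, stylized — gaps are
  widened relative to real tissue HU so that the window backend is a
  clean stand-in for a learned model).
* T1w-like: `t1 = 1045 − ct` for density-mapped tissues — a monotone
  *decreasing* map of tissue density, with fat fixed at the top of the
  scale, gallbladder just below it, and lungs near the bottom. The
  constant 1045 is calibrated to the realized volume maximum so that
  inversion within the volume range reproduces CT-like values inside
  the default windows. The lesion sits only 50 units below kidney
  parenchyma (≈ half the inter-organ spacing), keeping its T1w contrast
  subtle.
* T2wfs-like: water-rich structures (kidneys, spleen, gallbladder,
  lesion) highest; fat, bone and lung low (fat saturation).

Rendering composes: piecewise-constant means → smooth multiplicative
bias field (amplitude 1.5%, a cubic upsampling of a seeded 4³ Gaussian
grid) → Gaussian point-spread blur (σ = 0.75 mm) producing
partial-volume voxels at structure borders → background-air reset →
additive Gaussian noise (SD 8 intensity units, 1.5× in the lungs)
inside the body only. Background air is exactly 0 in the MR-like
volumes (−1000 in CT-like): an idealization of the tight, quantized
background plateau of magnitude MRI. This is what the value-threshold
reading of the background-zeroing rule relies on, and it makes the
"air is exactly 0 after inverted-black" property exact rather than
approximate. Lung means sit just above the threshold with higher noise,
so background zeroing clips some but not all lung voxels — inversion
artifacts in air-filled lungs are part of the emulated behavior.

What the phantom does *not* model: real anatomy and organ texture, MR
physics (no TR/TE, no coil profiles beyond the smooth bias field),
motion/fold-over artifacts, lesion heterogeneity, and inter-scanner
intensity variation. Passing tests therefore demonstrate the mechanism
and the pipeline's correctness, not clinical-grade accuracy.

## Evaluation and statistics

Per reference class, DSC = 2|A∩B|/(|A|+|B|); a prediction mask is the
union of all prediction classes mapped to that reference class (many-
to-one mapping, unmapped classes ignored). When both masks are empty
the DSC is undefined and excluded from means (its count reported)
rather than scored 1.0 — on synthetic cohorts a class can be genuinely
absent, and scoring absence as success would inflate means. Group means
default to pooling all (case, class) records; a per-class-then-average
alternative is available. 95% CIs come from a seeded case-level
percentile bootstrap (default B = 2000): cases, not records, are the
exchangeable unit.

Tumor localization uses the weakest defensible reading: any overlap
with the reference lesion counts as correctly localized, a non-empty
prediction with zero overlap as incorrect, an empty prediction as not
detected. A minimum-overlap-fraction flag (default 0) tightens this if
desired. The median-volume split assigns the exact-median record to the
upper stratum (arbitrary but fixed).

Paired comparisons between preprocessing variants use the Wilcoxon
signed-rank test on per-case units (mean DSC across classes, or the
lesion-class DSC), two-sided, zero differences dropped, exact null
distribution for ≤ 25 non-zero pairs and a continuity-corrected normal
approximation above. Shapiro–Wilk normality p-values are reported
descriptively rather than used to switch test families — the
nonparametric test is run throughout, avoiding an undocumented branch.
All comparisons emitted in one report form a single Benjamini–Hochberg
family. Spearman correlation uses mid-ranks for ties. The test engines
are scipy.stats and statsmodels; the package pins the conventions and
is verified against exhaustive sign-flip enumeration (n ≤ 10), a
hand-rolled BH step-up, and a paired-null calibration (raw
false-positive rate at n = 30 within [0.03, 0.07]).

## Pipeline and reproducibility

Experiments are YAML-configured (strict schema: unknown keys are
errors; relative paths resolve against the config file's directory).
Per case the pipeline resamples to the working resolution *before*
preprocessing (geometry first, then intensity), segments, and scores.
Backend failures are recorded per case and the run continues; more than
50% failures make the run fail. Every report carries a manifest
(config, config hash, package version, seeds); re-running from a
manifest's config reproduces all CSVs byte-identically (fixed float
formatting, seeded bootstrap, deterministic backend).

## Study problem sizes

The canonical desk-scale studies (`invertseg.experiments`) use a
72-voxel cubic grid at 2.5 mm spacing, a 1.5 mm working resolution,
n = 20 subjects for the variant grid and n = 30 for the lesion-volume
study with volumes log-uniform in 1–200 cm³ (sides drawn 45%/55%
left/right). These sizes were chosen so a full study runs in minutes on
one CPU while every effect of interest remains comfortably detectable;
the `PhantomSpec` default remains a 96³ grid at 2 mm. At the working
resolution, linear resampling adds partial-volume mixing at lesion
borders, which is the dominant driver of the lesion-volume/DSC
relationship: small lesions are mostly border.

## Known limitations

* The window backend measures intensity separability, not learned
  shape priors; its failure modes (thin false shells at high-contrast
  interfaces, gallbladder confusion with partial-volume fat) are
  plausible but not calibrated to any real model's errors.
* The T1w calibration constant couples the tissue table to the default
  window table; editing one usually requires revisiting the other.
* The phantom's left/right convention follows the canonical affine of
  its own outputs; external data with exotic orientations is reoriented
  on load, but oblique affines are handled only approximately by the
  axis-aligned resampler.
* Undefined-DSC exclusion means cohort means are computed over varying
  record counts when classes vanish (e.g. a lesion replacing an entire
  kidney); the per-group undefined count is reported so this is
  auditable.
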