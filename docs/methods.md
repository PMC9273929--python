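# Methods

## Measurement model

The quantity of interest is volumetric bone mineral density of the
vertebral trabecular compartment, in mg/cc of calcium-hydroxyapatite
equivalent. CT attenuation (HU) is assumed locally linear in equivalent
density for a given scanner and reconstruction; the internal calibration
estimates that line per scan from two tissue references:

    vBMD(H) = ρ_fat + (ρ_muscle − ρ_fat) · (H − H_fat) / (H_muscle − H_fat)

Assumptions: (1) fat and muscle equivalent densities are stable across
patients at the configured reference values; (2) the scanner response is
linear over the fat–bone HU range; (3) the tissue ROIs sample pure
tissue. Under these, the two-point line inverts the scanner map exactly,
which is why calibrated vBMD is device-independent while raw HU is not.
Violations (marrow fat variation, beam hardening, partial volume) enter
as bias the phantom study cannot see — see Limitations.

The reference equivalent densities are deliberately explicit config
constants (`calibration.rho_fat_mgcc = −50`, `rho_muscle_mgcc = +40`,
literature-range values for soft-tissue calibration). They are not
measured by this package, and any clinical deployment should treat them
as tunables to be validated against a phantom-based ground truth. The
synthetic scanner models are anchored to the same configured values so
end-to-end recovery on phantoms is exact by construction — the phantom
tests validate the pipeline's geometry and statistics, not the clinical
truth of the ρ references.

## Pipeline parameters

All tunables live in one `RunConfig` document (YAML-overridable); the
load-bearing ones:

| parameter | default | meaning |
|---|---|---|
| `roi.bone_threshold_hu` | 200 HU | marks vertebral bone for localization |
| `roi.cortical_threshold_hu` | 400 HU | shell level the trabecular ROI must avoid |
| `roi.margin_mm` | 3 mm | trabecular ROI clearance from cortical HU |
| `roi.slice_span_mm` | 9 mm | axial ROI extent, in mm so ROIs are volumetrically comparable across 1/3/5-mm protocols |
| `roi.fat_window_hu` | [−190, −30] | subcutaneous-fat candidate window |
| `roi.muscle_window_hu` | [10, 100] | paraspinal-muscle candidate window |
| `roi.muscle_lateral_max_mm` | 60 mm | paraspinal corridor half-width |
| `roi.tissue_bone_margin_mm` | 6 mm | tissue candidates keep this clearance from bone (low-density trabecular HU can fall inside the muscle window) |
| `roi.trim_fraction` | 0.05/tail | symmetric trim of ROI HU values |
| `roi.min_roi_voxels` | 50 | below this an ROI is flagged unreliable |
| `calibration.min_tissue_contrast_hu` | 10 HU | reject scans with degenerate fat/muscle contrast |
| `classification.*` | 80/120 mg/cc, −2.5/−1.0 T | ACR and WHO thresholds |

Boundary conventions: QCT osteoporosis is strictly below 80 mg/cc and
osteopenia is the closed interval [80, 120] (the volumetric criteria
leave the endpoints ambiguous; this choice is documented and encoded in
one place). DXA boundaries are inclusive as the WHO wording states
(T ≤ −2.5, −2.5 < T ≤ −1.0).

## Localization and ROI placement

Vertebral localization is a deterministic substitute for the trained
selector used clinically (whose training procedure is external to this
package): threshold bone, restrict to a posterior-midline corridor
centered on the median bone column, mark slices whose corridor bone area
exceeds 50 mm², and read contiguous z-runs as vertebral bodies separated
by disc gaps. Bodies are counted caudally from the most cranial fully
imaged body, whose label is configurable (`roi.top_level`, default T12
for a chest scan whose last complete body is T12); runs touching the
scan boundary are treated as partial. The mid-body slice is the median
slice of the run.

The trabecular ROI is a circle centered on the body centroid whose
radius is the distance to the nearest cortical-level voxel minus the
safety margin, capped at 10 mm — by construction no ROI voxel lies
within the margin of cortical HU. Tissue ROIs: HU-window candidate
masks, opened (3×3) to remove noise speckle, closed to suppress
pinholes, and restricted anatomically (muscle: within 60 mm of the
midline, posterior to the vertebral centroid, split left/right; fat: the
subcutaneous band); the largest component per region receives the
largest inscribed circle scaled by 0.8. Muscle HU enters the calibration
as the unweighted mean of the left and right ROI means. ROI statistics
use a 5%-per-tail trimmed mean (unbiased under symmetric noise, robust
to stray dense/airy voxels).

Numerical determinism: component ties resolve to the first label in
raster order; the inscribed-circle center is the first EDT argmax; all
randomness in generators flows from a single integer seed.

## What the phantom emulates — and what it does not

The digital phantom is an axial chest section: air background, two lung
fields (−800 HU), soft-tissue thorax (+5 HU), a 10-mm subcutaneous fat
band, two paraspinal muscle ellipses, and vertebral bodies (27 mm tall,
14 mm outer radius, 2.5 mm cortical shell) separated by 10-mm discs.
Fat, muscle and trabecular HU come from the scanner model
HU(ρ) = a·ρ + b; four synthetic scanners with distinct (a, b) stand in
for device heterogeneity. Noise is additive i.i.d. Gaussian in HU.

The soft-tissue compartment is set to +5 HU, just below the muscle
window: real soft tissue overlaps muscle attenuation, and separating
them is exactly the job of the trained selector this package replaces
with geometry heuristics. The phantom therefore tests ROI geometry,
calibration algebra and statistics — not tissue-discrimination power on
real anatomy. Likewise absent: beam hardening and scatter (the artifacts
phantom-less calibration sidesteps clinically), partial-volume blur,
marrow-fat effects, anatomical variation, spine curvature, osteophytes
in the CT image itself. Passing phantom tests shows the pipeline is
correct under its stated model, not that it is clinically accurate.

## Cohort simulator

Ages are Normal(57.99, 11.54) clipped to [20, 95]; sex is Bernoulli with
female fraction 383/649; anthropometrics follow the sex-stratified
means/SDs of the clinical cohort table. True trabecular density is drawn
per decade bin: bin means decline linearly from the 30–39 endpoint to
the 80+ endpoint (women 155.19 → 66.59 mg/cc, men 161.7 → 72.2; the
under-30 bin sits at the ~160 mg/cc young-adult level), SD 25 mg/cc.
QCT adds 5 mg/cc measurement noise. The DXA linkage is the affine map
taking 80 mg/cc to T = −2.5 and 120 mg/cc to T = −1.0 (so noise-free,
uninflated records classify identically under both criteria) plus
0.3 T noise per site; an age-increasing fraction of patients
(8% at age 40, +0.5%/year, capped at 40%) has all DXA T-scores inflated
by U(0.5, 2.5) — the osteophyte/vascular-calcification mechanism that
produces DXA false negatives and makes QCT flag a higher osteoporosis
proportion than DXA. The linkage and inflation magnitudes are modelling
conveniences chosen to keep category prevalences plausible (~12%
osteoporosis), not measured quantities. Exclusion flags are Bernoulli by
default, or exact disjoint counts for reconstructing a screening flow.

## Problem sizes

Default phantoms are 32×96×96 voxels at 3×1.5×1.5 mm (a 96-mm axial
window around T12 — all the pipeline needs), which keeps a full
measurement under ~20 ms. The acceptance script uses 30 phantoms per
stratum at 10-HU noise; with trabecular/tissue ROIs of ~100–300 voxels
the per-phantom vBMD error is ~1–1.5 mg/cc SD, so stratum means are
reproducible to well under 1 mg/cc.

## Known limitations

- ρ references are constants, not per-patient estimates; age/sex
  adjustment of the references is unimplemented.
- Calibration is per-volume at the measured level, not per-slice.
- Only axial, orthogonal volumes are supported; oblique acquisitions are
  rejected rather than resampled, and volumes are never resampled across
  slice thicknesses.
- The vertebral counter needs the requested level's body fully imaged
  and labels it by position, so the configured `top_level` must be
  correct for the scan protocol.
- Hip/femur measurement, cortical-bone BMD, dual-energy decomposition
  and marrow-fat correction are out of scope.
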