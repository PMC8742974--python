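# Methods

## Scope and model

`trabscope` studies how measured ventricular trabeculation depends on
imaging resolution. Because no deposited imaging data exist for this
problem at the required ground-truth fidelity, the package measures
*synthetic phantoms whose trabecular structure is exact by construction*.
Every downstream number — counts, layer ratios, compartment volumes,
diagnostic calls, ANOVA p-values — is therefore checkable against a known
truth.

Two phantom families cover the two kinds of measurement:

**Whole-ventricle phantom** (`generate_phantom`). The LV is a truncated
prolate half-ellipsoid: epicardial semi-axes (R, L), compact shell bounded
by an inner offset ellipsoid with semi-axes (R − c, L − c). On the luminal
side, `n_trabeculations` radial ridges of physical width drawn from
`trabeculation_width` are placed at even angular pitch, *detached* from the
shell by an intertrabecular recess (`recess_gap`) and extending
`trabeculation_depth` toward the lumen; ridges end apexward where either
the free lumen core or the inter-ridge clearance would vanish, so the truth
stays representable on the grid. A configurable angular sector carries no
ridges (the smooth outflow tract). Papillary muscles are vertical cylinders
at half the local endocardial radius, labelled as trabecular tissue (they
derive from embryonic trabecular muscle and count toward trabecular
volume); a clearance shell (default 1.2 mm, wider than the coarsest
in-plane voxel simulated) is carved between papillary columns and ridge
tips so the structures remain separable after partial-volume degradation.
An optional RV crescent (cavity depth tapering sinusoidally over its
angular span, thin compact free wall, luminal ridges) attaches to the LV
epicardium; its insertion angle defines θ = 0 for segment numbering.
Intertrabecular recesses are always lumen, never tissue.

Counting semantics: radial (transmural) rays in this phantom cross one
detached ridge, so `n_trabeculations` is defined as the count on a
*circumferential* trajectory through the mid-trabecular layer of a
short-axis ring — the number of ridges on the ring. Transmural rays carry
the thickness measures C, NC and T/C.

**Transmural slab sample** (`generate_transmural_sample`). For the
resolution experiment the natural object is a transmural tissue block in
which an epicardium-to-endocardium line crosses many trabecular profiles.
The slab stacks, along the transmural axis x: a compact layer, then
`n_trabeculae` trabecular sheets separated by recesses, then lumen. Sheet
widths and recess gaps are drawn per sheet (defaults 0.4–2.0 mm and
0.3–1.5 mm — fractions of a millimetre up to a few millimetres, with
recesses narrower than the clinical in-plane voxel, which is what makes the
experiment informative). Each sheet covers a random sub-interval of the
lateral (y) extent, and the whole structure is sheared (slope 0.1–0.3, sign
random) so sheets meet the section obliquely: transmural run lengths are
unchanged by the shear (boundaries are planes x = b + s·y), but two distinct
trajectories see the structure at different positions relative to the voxel
grid, as distinct locations on a real section would. z (slice direction) is
uniform.

## Imaging model

Degradation to a stated resolution is separable **box averaging**: each
output voxel holds the volume-weighted myocardium fraction of the source
voxels it covers. Box averaging is chosen over windowed-sinc interpolation
because it carries an exact conservation contract (Σ intensity × voxel
volume equals true tissue volume up to edge truncation of less than one
voxel layer), which the partial-volume experiments rely on. Upsampling is
rejected. The named conditions are 0.5 × 0.5 × 0.5 mm³ ("mri_high") and
1.5 × 1.5 × 8.0 mm³ ("mri_clinical", 8 mm always the base→apex axis, as in
clinical short-axis stacks); histology-like imaging is 2D section rendering
at 258 px/mm. Optional seeded Gaussian intensity noise is available
(default 0). Binarization thresholds the fractional intensity at 0.5 by
default — unbiased for a two-class partial-volume mixture — and is exposed
because no canonical value exists.

Trajectory measurements on MRI-resolution images are read, by default, off
the *grayscale* image: the profile is sampled with trilinear interpolation
and tissue is wherever intensity reaches 0.5, locating run boundaries with
sub-voxel precision. This emulates a reader measuring on the displayed
image (the original readings were made on grayscale images in ImageJ)
rather than on a hard-thresholded mask; the thresholded path
(`extract_profile` on a binarized volume) is also provided and is used for
all volumetric/labelling operations. Both paths show the same merging
mechanism; the grayscale path removes the ±half-voxel quantization noise of
mask-based thickness reading.

## Measurements

* **Profiles**: straight rays from outside the epicardium toward the lumen
  centroid (slab: along +x), sampled at a quarter of the smallest voxel
  dimension, run-length encoded from the first myocardial sample.
* **C, NC, T/C**: C is the first myocardial run; NC spans from the end of
  that run to the end of the last myocardial run — recesses are *included*
  in the span (thickness criteria are layer-extent measures) although they
  are *excluded* from trabecular volume (the volume criterion is a tissue
  measure); the two conventions coexist deliberately. Trabeculations that
  merge into the compact wall at coarse resolution thicken the apparent C —
  that is the mechanism under study, not an artifact to correct.
* **Count**: myocardial runs after the first. An independent oracle
  (`count_runs_brute_force`) counts connected intervals directly on the
  boolean sample sequence.
* **Compartment classification**: per short-axis slice, dense rays from the
  cavity centroid (one per ≤ 0.5 voxel of boundary arc, samples every
  quarter voxel); each ray's first myocardial run from outside is compact,
  all other myocardium trabecular, recesses stay lumen. Ties resolve toward
  compact (conservative for ET calls). Slices whose ring fails to enclose
  the cavity are flagged (`gap_slices`), not silently classified.
* **Cavalieri volumes**: `n_slices ≥ 10` equidistant planes over the
  tissue-bearing extent, midpoint rule, V = Σ A·d. Exact for constant-area
  stacks; O(d²) convergent otherwise.
* **17 segments**: landmarks are the axial extremes of LV tissue and of the
  papillary label (papillary extent comes from the generator truth when
  available, otherwise from a geometric detector: trabecular components
  whose mean radius is under half the local endocardial radius). Analysis
  slices are the floor midpoint of flanking landmarks (ties toward the
  base — a deterministic choice, nothing canonical exists). Zone mapping:
  base-most→tips = basal (segments 1–6, 60° sectors from the reference
  angle), tips→papillary-base = mid (7–12), papillary-base→apex-most =
  apical (13–16, 90°); slices with no remaining lumen form the apical cap
  (17). Per-segment T/C is the *maximum* over that segment's trajectories
  (matching how a worst-segment criterion is applied); segment 17 is
  excluded from summed/average T/C.
* **Papillary avoidance**: thickness trajectories that cross a papillary
  muscle would read the span to the papillary's inner edge, which is not
  what thickness criteria measure. Papillary angular zones are detected on
  the measured image (trabecular components confined within 70 % of the
  local endocardial radius) and trajectories inside those zones are
  skipped. Papillary tissue still counts fully toward trabecular volume.
* **Diagnostics**: strict inequalities (T/C > 2.3 in ≥ 1 of segments 1–16,
  or trabecular fraction > 25 %); equality is negative. ET iff either
  criterion fires. "Abnormal but ET-negative" is an input annotation — the
  morphologies that make a heart abnormal are qualitative and not
  computable from the two criteria.

## Statistics

The two-factor (sample, resolution) ANOVA is a fixed-effects,
no-interaction decomposition computed from closed-form sums of squares
(SS_total = SS_sample + SS_resolution + SS_residual holds exactly; verified
against `statsmodels.anova_lm`). Trajectories are averaged within
sample × resolution cells by default (one observation per cell, no
interaction estimable); treating them as replicates of the balanced
no-interaction model is a switch. The 2×2 chi-square uses the Pearson
shortcut formula without continuity correction by default (the corrected
variant, available by flag, changes the statistic substantially for sparse
tables). The LV–RV model is OLS of LV trabecular volume on LV compact, RV
trabecular and RV compact volumes; standardized betas are β·sd(x)/sd(y),
residuals are screened against ±3 standardized units, and the Shapiro–Wilk
normality p of the dependent variable is always reported while the fit
proceeds regardless (a reported gate, not a hard stop).

## Study conditions and sizes

The resolution experiment uses 12 samples × 2 trajectories × 3 resolutions
(the ex-vivo protocol's shape). Per-sample free parameters not fixed by the
protocol are drawn once: compact thickness U(6, 12) mm (normal through
thin-walled dilated hearts), 4–12 trabeculae per trajectory. The cohort
study defaults to 6 normal / 7 abnormal / 4 ET hearts; the LV–RV study to
17 hearts with an optional latent-factor coupling between LV and RV
trabecular extent (0 = independent, the default).

Cohort phantoms are *scaled-down* hearts (epicardial radius 13–19 mm,
generated at 0.15 mm isotropic; widths are kept ≥ 3 generation voxels so
the truth is representable) — absolute volumes are accordingly about an
order of magnitude below adult values, while the ratio and fraction
measures the criteria use are scale-free. Class parameters were set from
the diagnostic thresholds with deliberate margins: normal ≈ T/C 0.65,
fraction ≈ 10 %; abnormal ≈ T/C 1.6, fraction ≈ 16 %; ET ≈ T/C 3.0,
fraction ≈ 30 % — so normal/abnormal sit clearly below both thresholds and
ET clearly above at least one (in practice both).

## What the phantoms do and do not emulate

They emulate the geometry the measurements see: a two-layer wall,
sub-voxel trabeculae and recesses, papillary muscles, a smooth outflow
tract, an RV crescent, short-axis stack anisotropy, and partial-volume
merging. They do not emulate histological texture (tissue is binary),
fibrosis, contraction state, post-mortem deformation, autopsy cuts, MRI
physics (relaxation weighting, coil sensitivity, Rician noise), or the
tangled three-dimensional anastomosing meshwork of real trabeculation —
ridges and sheets here are regular. Passing tests therefore demonstrate
that the *measurement pipeline* behaves correctly and that resolution
effects of the expected direction and magnitude arise from geometry alone;
they do not calibrate absolute prevalences or reproduce any specific
heart's values.

## Numerical choices and degenerate inputs

Coordinates are physical millimetres, voxel centres at (i + 0.5)·spacing,
0-based indices, half-open spans. Profile sampling at min(voxel)/4; ray
density for classification at 0.5 voxel of arc. Empty trajectories raise
`EmptyProfileError`; broken rings are flagged; fewer than 10 Cavalieri
slices, upsampling requests, overlapping ridges (angular pitch < width),
zero-variance correlation inputs, empty chi-square margins and
under-determined regressions are rejected with explicit errors. All
randomness flows from one integer seed per object through
`numpy.random.default_rng`; experiment reports regenerate byte-identical
CSVs from (config, seed), and figures are written without timestamps.

## Known limitations

* The abnormal phantom class is a quantitative intermediate; it does not
  model the qualitative morphologies (crossing trabeculations, clefts,
  even-sized trabeculations) that make real hearts abnormal.
* RV compartment classification reuses the LV ray-casting machinery from
  the crescent cavity's centroid; it is adequate for volumes but less
  validated than the LV path (no analog of the LV labelling sweep).
* Whether per-segment T/C should be the maximum or a representative value
  along the segment is ambiguous in clinical practice; the maximum is
  implemented.
* Straight trajectories only; real readers sometimes bend trajectories
  around papillary muscles instead of skipping them.
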