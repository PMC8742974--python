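# trabscope

Resolution-aware morphometry of ventricular trabeculation on synthetic
phantoms.

## The problem

The inner surface of the human ventricular wall is lined with trabeculations
— muscular ridges whose widths range from a fraction of a millimetre to a
few millimetres. Left-ventricular "noncompaction" (more neutrally, excessive
trabeculation, ET) is diagnosed from the relative extent of the trabecular
and compact layers: a trabecular-to-compact thickness ratio **T/C > 2.3**
along a transmural line in any of segments 1–16 of the clinical 17-segment
model (Petersen-type criterion), or a trabecular volume **> 25 %** of total
LV wall volume (Grothoff-type criterion, papillary muscle included,
intertrabecular recesses excluded). Both quantities are measured on images —
and clinical MRI voxels (≈1.5 × 1.5 × 8 mm³) are larger than many
trabeculations, so partial-volume blending merges thin trabeculae into the
apparent compact wall. How much the *measured* trabeculation depends on
spatial resolution is a confound for reported prevalences and for the
criteria themselves.

`trabscope` makes that question computable. It generates ventricular-wall
phantoms with exactly known trabecular structure, degrades them to stated
acquisition resolutions with mass-conserving box averaging, and applies the
standard measurement battery:

* transmural profiles: compact thickness `C` (first myocardial run from the
  epicardium), trabecular span `NC` (end of the compact run to the last
  myocardial run, recesses included in the span), `T/C = NC/C`, and the
  trabeculation count (myocardial runs after the first);
* compartment labelling (compact vs trabecular) by dense ray casting, and
  compartment volumes by the Cavalieri principle, `V = Σᵢ Aᵢ · d` over ≥ 10
  equidistant short-axis planes;
* the 17-segment model from four landmark slices (basal-most LV, papillary
  tips, papillary base, apex-most), analysis slices midway between
  landmarks, per-segment max T/C;
* the ET criteria (strict inequalities) and cohort summaries;
* the statistical battery: two-factor (sample × resolution) fixed-effects
  ANOVA, Pearson correlations with Bonferroni correction (α/16), Pearson
  2×2 chi-square (shortcut formula `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`), and
  OLS of LV trabecular volume on LV-compact/RV-trabecular/RV-compact volumes
  with standardized betas, a Shapiro–Wilk normality report and a ±3
  standardized-residual screen.

## Worked example

A transmural wall sample with 8 trabecular sheets (widths 0.4–2 mm, recesses
0.3–1.5 mm) is measured along the same physical trajectory at three
resolutions:

```python
from trabscope import (TransmuralSampleSpec, generate_transmural_sample,
                       RESOLUTIONS, resample, axial_trajectory,
                       render_histology_section, section_as_volume,
                       extract_profile, measure_layers)
from trabscope.morphometry import extract_profile_intensity

spec = TransmuralSampleSpec(compact_thickness=8.0, n_trabeculae=8, seed=3)
vol, truth = generate_transmural_sample(spec)
y = vol.extent_mm()[1] / 2
print(f"truth: count={truth.count_at(y)}  C={truth.compact_thickness:.2f} mm  "
      f"NC={truth.nc_at(y):.2f} mm  T/C={truth.tc_at(y):.2f}")

sec = section_as_volume(render_histology_section(vol, px_per_mm=258.0))
m = measure_layers(extract_profile(
    sec, axial_trajectory(sec, y_mm=y, z_mm=sec.spacing[2] / 2)))
print(f"histology (258 px/mm): count={m.count}  C={m.C:.2f}  "
      f"NC={m.NC:.2f}  T/C={m.TC:.2f}")

for name in ("mri_high", "mri_clinical"):
    iv = resample(vol, RESOLUTIONS[name])
    z = min(vol.extent_mm()[2] / 2, iv.extent_mm()[2] - iv.spacing[2] / 2)
    m = measure_layers(extract_profile_intensity(
        iv, axial_trajectory(iv, y_mm=y, z_mm=z)))
    print(f"{name}: count={m.count}  C={m.C:.2f}  NC={m.NC:.2f}  T/C={m.TC:.2f}")
```

prints

```
truth: count=8  C=8.00 mm  NC=15.56 mm  T/C=1.94
histology (258 px/mm): count=8  C=8.00  NC=15.60  T/C=1.95
mri_high: count=8  C=8.00  NC=15.50  T/C=1.94
mri_clinical: count=2  C=8.25  NC=13.12  T/C=1.59
```

At histology-like and 0.5 mm resolution all eight trabeculations are
recovered; at clinical-like resolution six of them merge (count 8 → 2), the
apparent compact wall thickens and T/C falls — exactly the partial-volume
mechanism that makes measured trabeculation resolution-dependent.

## Command line

```bash
trabscope phantom --spec spec.yaml --seed 17 --out out/      # NIfTI + truth JSON
trabscope image --in out/phantom.nii.gz --res mri_clinical --out low.nii.gz
trabscope measure --in low.nii.gz --slices 10 --out volumes.csv
trabscope run resolution|cohort|lvrv --seed 1 --out results/
```

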