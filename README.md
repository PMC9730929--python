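# petmip

Surrogate whole-body PET lymphoma biomarkers computed from two 2D
maximum-intensity projections (MIPs), with their 3D reference counterparts,
pluggable 2D lesion segmenters, and the downstream prognostic analysis.

## The problem

In diffuse large B-cell lymphoma (DLBCL), two quantities measured on the
baseline ¹⁸F-FDG PET scan are strong prognostic biomarkers:

* **TMTV** (total metabolic tumor volume, cm³) — the summed volume of all
  delineated lesions, and
* **Dmax** (cm) — the largest distance between two lesions, a measure of
  disease dissemination.

Both require lesion delineation over the full 3D volume (hundreds of slices),
which is slow and observer-dependent.  An attractive shortcut is to work on
the two MIP views (coronal and sagittal, 90° apart) that physicians already
use for reading, and replace the 3D biomarkers with 2D surrogates:

* **sTMTV** (cm²) = lesion-pixel count × pixel area, summed over the coronal
  and sagittal MIP masks: `sTMTV = sTMTV_cor + sTMTV_sag`;
* **sDmax** (cm): per view, reduce the MIP mask to its column-sum (x) and
  row-sum (y) profiles, take the distance between the 2% and 98% percentiles
  of each profile's cumulative mass, and sum:
  `sDmax_view = (x₉₈ − x₂) + (y₉₈ − y₂)`, `sDmax = sDmax_cor + sDmax_sag`.
  The 2%/98% percentiles make the distance robust to stray outlying pixels.

This package implements the full chain — NIfTI I/O, MIP projection, the four
biomarkers, a deterministic baseline segmenter and a compact trainable
encoder–decoder for MIP lesion segmentation with patientwise 5-fold
cross-validation, agreement statistics (Dice/sensitivity/specificity,
Wilcoxon, Spearman, median-split concordance, 3-category risk agreement), and
survival analysis (Kaplan–Meier, Cox hazard ratios with bootstrap CIs,
IPCW time-dependent AUC, TMTV×Dmax risk stratification) — and, because no
public imaging exists for such cohorts, a synthetic whole-body phantom
generator (warm body, hot brain/heart/bladder analogues, ellipsoidal lesions,
truncated Gaussian noise) with analytic ground truth and linked simulated
survival outcomes, so every stage is testable end to end.

## Worked example

```bash
petmip segment --n 15 --seed 2
```

generates 15 phantom patients, segments their MIPs with the baseline
thresholder, and compares the segmenter-derived surrogate biomarkers with
those from the reference masks:

```
median Dice vs reference: 0.956
Spearman sTMTV: 0.921  sDmax: 0.988
3-category risk agreement accuracy: 0.733
```

i.e. on these phantoms the automatic masks agree with the reference at
Dice ≈ 0.96, the surrogate biomarkers derived from them rank patients nearly
identically (Spearman r ≥ 0.92), and 73% of patients land in the same
low/intermediate/high risk category under both routes.

The same from Python:

```python
from petmip.phantom import generate_cohort
from petmip.projection import make_mip_pair
from petmip.biomarkers import compute_record

case = generate_cohort(1, seed=7)[0]
rec = compute_record(case.patient_id, case.mask, make_mip_pair(case.volume, case.mask))
print(f"TMTV={rec.tmtv_cm3:.1f} cm3  Dmax={rec.dmax_cm:.1f} cm  "
      f"sTMTV={rec.stmtv_cm2:.1f} cm2  sDmax={rec.sdmax_cm:.1f} cm")
# TMTV=80.5 cm3  Dmax=34.7 cm  sTMTV=91.7 cm2  sDmax=89.6 cm
```

The full pipeline (biomarker CSV, exclusion log, survival JSON, manifest):

```bash
petmip run-all --n 20 --seed 1 --out run1
```

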