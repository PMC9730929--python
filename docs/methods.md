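# Methods

This note documents the models, conventions and numerical choices behind
`petmip`, in the spirit of the methods documentation of packages such as
statsmodels or scanpy: what is computed, under which assumptions, and which
choices were genuinely open.

## Axis and unit conventions

All 3D grids use a fixed anatomical axis order — axis 0 left–right (LR),
axis 1 anterior–posterior (AP), axis 2 inferior–superior (IS), i.e. RAS+
voxel order.  NIfTI files in any orientation are reoriented to this
convention on read (nibabel's closest-canonical transform); the original
orientation is retained for round-tripping.  Spacing is carried in mm and
never resampled: anisotropic voxels flow through every computation, so MIP
pixel area is `u·v` mm² per view.  Internally everything is mm; reported
biomarkers are cm (distances), cm² (surrogate burden) and cm³ (volume).

The coronal view projects along AP (image axes LR×IS) and the sagittal view
along LR (image axes AP×IS); there are exactly two views, 90° apart, and the
surrogate definitions are tied to them.

## Biomarkers

* **TMTV** = lesion voxel count × voxel volume.  The lesion mask is an input
  (the expert-validated delineation in clinical use; the phantom ground truth
  here) — lesion delineation in 3D is out of scope.
* **Dmax** = the largest Euclidean distance between lesion centroids.
  Lesions are 26-connected components of the merged mask (the most inclusive
  standard 3D connectivity; chosen explicitly since nothing forces a
  convention), and a centroid is the mean of member voxel centers
  (`(index + ½)·spacing`) in physical mm.  Patients with fewer than two
  lesions get Dmax = 0 plus an `n_lesions<2` flag; excluding them is a
  cohort-policy decision made at the pipeline level so the library functions
  stay total.
* **sTMTV** per view = MIP-mask pixel count × pixel area; total = coronal +
  sagittal component.
* **sDmax** per view = x-profile span + y-profile span, where the profiles
  are the column and row pixel sums of the MIP mask and a span is the
  distance between the 2% and 98% percentiles of the profile's cumulative
  mass.  Total = coronal + sagittal component.

**Percentile convention.** The profile is a discrete mass function over bin
indices; `q(p)` is the smallest bin index whose cumulative fraction reaches
`p` (left-continuous discrete quantile, no interpolation), and the span is
`(q(0.98) − q(0.02)) × spacing`.  This makes degenerate cases exact — a
single-bin profile has span 0, an empty profile 0 — and is directly checkable
against a brute-force cumulative scan.  Whether interpolation was intended in
the original definition is not documented anywhere we could verify, so the
convention is stated here as this package's choice rather than asserted as
canonical.

Useful invariants, all covered by tests: totals are exactly the sum of the
two view components; doubling all spacings multiplies TMTV by 8, sTMTV by 4
and Dmax/sDmax by 2 exactly; projections never create unsupported pixels;
adding lesion voxels never decreases burden.

## Synthetic phantoms

The generator emulates the geometry and intensity ordering of a whole-body
FDG-PET study, not its physics.  A case consists of:

* a body envelope (elliptic-cylinder trunk + ellipsoidal head) at unit
  background uptake;
* physiologic hot organs excluded from the lesion mask — brain (8× background),
  heart (5×) and bladder (10×) analogues — present precisely so segmenters can
  fail realistically on non-tumor uptake;
* 1–10 ellipsoidal lesions, radii log-uniform on 6–24 mm, uptake uniform on
  4–9× background, placed inside the trunk.  Across a cohort the true TMTV
  spans more than an order of magnitude, which is what makes rank-correlation
  studies meaningful;
* additive Gaussian noise (σ = 0.1 background units by default), truncated at
  zero.

The default grid is 64×48×160 voxels at 4 mm isotropic spacing — a compact
whole-body-like matrix at PET-typical resolution.  A voxel belongs to an
ellipsoid iff its center lies inside it; ground truth carries the analytic
ellipsoid volumes (4/3·π·abc), centers, and the analytic largest pairwise
center distance, so voxelization error is measurable (≈5% for a 10 mm sphere
at 2 mm spacing, shrinking with finer spacing).  Generation is byte-identical
under a fixed seed.

What the phantoms do **not** model: point-spread blur, scatter, partial
volume, reconstruction noise correlation, lesion texture, or anatomical
variability.  Tests passing on phantoms therefore demonstrate the
correctness of the geometry and statistics, and the learnability of the
segmentation task under idealized contrast — not clinical performance.

Survival outcomes are simulated from an exponential proportional-hazards
model `h(x) = h0 · exp(Σ βⱼxⱼ)` (default h0 = 0.01 events/month; covariates
entered as cohort z-scores of log1p biomarkers, or as raw/binary columns),
with independent uniform censoring on (0, horizon] applied with a configured
probability (default 0.2, horizon 60 months).  The closed form gives exact
checks: Kaplan–Meier recovery of `exp(−h0·t)` under β = 0, and Cox recovery
of a known hazard ratio.

## Segmentation

Two interchangeable segmenters map one MIP image (either view) to a binary
mask of the same shape.

**Baseline thresholder.**  A pixel is a lesion iff its intensity strictly
exceeds `lo + threshold·(hi − lo)` where `lo` is the 1st intensity percentile
and `hi` is the maximum of the 3×3-median-filtered image.  The median-filtered
maximum is the "robust max": an isolated noise spike cannot set it, while any
lesion plateau of a few pixels can — a fixed high percentile would fail
whenever lesions occupy a tiny fraction of the image.  Optional
physiologic-region templates (projected organ masks, dilated by one pixel)
are excluded both from the candidates and from the robust-range estimate,
mirroring how readers discard physiologic uptake.  The segmenter is pure and
deterministic; on high-contrast low-noise phantoms it exceeds Dice 0.9 and it
degrades, in expectation, as noise grows.

**Encoder–decoder CNN.**  A compact three-level U-Net-style network
(conv3×3-ReLU blocks, 2× average pooling, nearest-neighbor upsampling with
skip concatenation, 1×1 output head; ≈7k parameters at the default base
width 8) implemented directly on numpy — im2col convolutions, hand-derived
backpropagation (verified against central finite differences in the tests)
and Adam.  Inputs are clipped at the 99.9th intensity percentile, scaled to
[0, 1], and stacked with a vertical-coordinate channel so the network can
learn the axial position of physiologic hot regions; images are mapped to a
fixed 64×64 grid by aspect-preserving resize + zero-padding and predictions
are mapped back by the inverse transform (bilinear for probabilities, then
thresholded at the configured cutoff, default 0.5).  The loss is soft Dice
plus a binary cross-entropy whose lesion pixels are upweighted (default 8×):
with sparse masks an unweighted loss collapses to the empty prediction, and
the output bias starts at −2 (near the lesion prior) so the sigmoid is not
saturated at initialization.  Defaults (learning rate 2·10⁻², batch 4) were
chosen so that the scaled-down protocol — 60 phantom patients, both views as
independent samples, 10 epochs — trains in seconds per fold on one CPU.

**Evaluation protocol.**  Cross-validation folds are assigned per patient
(both views of a patient share a fold, never straddling train/validation);
5 folds of equal size ±1, deterministic under a seed.  Per-patient metrics
pool TP/FP/TN/FN pixel counts over both views before forming Dice,
sensitivity and specificity (pooling, rather than averaging per-view ratios,
is this package's documented reading of "patientwise"; it is configurable in
the sense that per-view metrics are also reported).  A patient with an empty
reference and an empty prediction has Dice 1 (agreement on absence) and is
flagged.

## Statistics

* **Wilcoxon signed-rank** (paired): zero differences dropped; for n ≤ 12 the
  two-sided p-value is exact by full enumeration of the 2ⁿ sign patterns
  (mid-ranks under ties, so the enumeration remains the exact permutation
  null); beyond that, scipy's tie-corrected normal approximation with
  continuity correction.
* **Spearman** correlation is tie-aware (mid-ranks), p from the
  t-approximation, via scipy.
* **Median-split concordance**: of the patients strictly above the median of
  one biomarker, the fraction also strictly above the median of the other
  (midpoint median for even n).
* **Risk agreement**: 3×3 confusion matrix (rows = reference categories) and
  its diagonal fraction.
* **Kaplan–Meier** estimation and the log-rank statistic go through
  lifelines.
* **Cox hazard ratio**: single-covariate partial likelihood with Breslow tie
  handling, maximized by a vectorized Newton iteration (risk-set sums as
  cumulative sums after sorting by descending time; steps clipped to ±2,
  |β| capped at 20 under complete separation).  The fitter agrees with
  scikit-survival's Breslow implementation to 10⁻¹⁵ and with a brute-force
  grid search to the grid step; it is written in-package because the
  bootstrap protocol refits it thousands of times.  Confidence intervals are
  percentile bootstrap over patients (default 1000 resamples, mandatory
  seed); a binary group with no events is flagged non-estimable rather than
  fitted.
* **Time-dependent AUC**: cumulative/dynamic at a fixed horizon (default 48
  months), with inverse-probability-of-censoring weights from the
  Kaplan–Meier estimate of the censoring distribution (cases weighted by
  1/G(T⁻), controls by 1/G(τ); marker ties count ½).  Under zero censoring
  all weights are 1 and the statistic reduces exactly to the pairwise rank
  AUC, which is the anchor the tests exploit; under censoring it agrees with
  scikit-survival's estimator to well under a percent.
* **Risk stratification**: low = both biomarkers ≤ their cutoffs, high = both
  above, intermediate otherwise; the boundary value is low (≤).  Cutoffs can
  be supplied, taken as the sample median, or chosen to maximize the two-group
  log-rank statistic over the inner-decile candidates — how published cutoff
  values were originally derived is typically unstated, so all three routes
  are explicit.

## Problem sizes and determinism

The test suite and the acceptance script run cohorts of 8–60 phantoms
(50 for correlation studies, 60 patients/120 view-samples for the CNN
cross-validation, 200 for the survival analysis, n = 500 × 100 replicates for
bootstrap-coverage checks), sizes chosen so the whole analysis reruns from
scratch in a few minutes on a single CPU while leaving every statistical
conclusion stable under the seed.  Every stochastic stage takes an explicit
seed; the pipeline manifest records config, seeds and version, and two runs
with the same manifest are byte-identical.

## Known limitations

* Phantom realism is geometric, not physical (see above); segmentation
  performance on phantoms does not transfer to clinical images.
* The CNN is a compact CPU-sized network; it preserves the contract of the
  published MIP-segmentation approach (2D in, binary mask out, one model for
  both views, patientwise CV) but not any specific published architecture or
  weights.
* Cox modelling is univariate (dichotomized or continuous single covariate);
  multivariate models with clinical covariates, competing risks and IPI
  modelling are out of scope.
* DICOM ingestion and SUV conversion are out of scope: inputs are NIfTI
  volumes in arbitrary consistent uptake units, and all biomarkers here are
  geometry-only, hence unit-agnostic.
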