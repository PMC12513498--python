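# Methods

## The measurement

AA-FAI treats perivascular fat as an inflammation sensor. Adipocytes near
an inflamed vessel shift from lipid (~−100 HU) toward water (0 HU), so the
mean attenuation of perivascular fat rises. The pipeline:

1. **Segmentation.** The ascending aorta is delineated per slice. The
   built-in classical detector thresholds at the contrast-lumen HU
   (default 150), labels connected components, keeps components whose
   equivalent radius lies in 10–25 mm with isoperimetric circularity
   ≥ 0.8, and tracks the component nearest the previous slice's centroid
   (first slice: most circular; ties broken by higher circularity, then
   smaller row coordinate — fully deterministic). The mask is the
   hole-filled component. External masks (label volumes or per-slice
   polygons) can replace the detector, which is how output of a trained
   CNN would be consumed.
2. **Extent.** Analysis covers `ceil(extent_mm / slice_thickness)`
   contiguous slices from the first detected slice (default 50 mm → 10
   slices at 5 mm), truncated at the volume end with a flag.
3. **Ring.** Per slice, in 2-D: a pixel is perivascular iff it is outside
   the vessel mask and the Euclidean distance from its centre to the
   nearest vessel-pixel centre is ≤ 10 mm, computed with the true row and
   column spacing (anisotropy handled by the sampled distance transform).
4. **Fat window.** Ring pixels with attenuation in **[−190, 0] HU**,
   bounds inclusive, are ct-PVAT.
5. **Statistic.** AA-FAI is the *pooled* mean over all fat pixels of all
   analyzed slices — one sum divided by one count, not a mean of per-slice
   means, so slices with more fat weigh more. ct-PVAT area is the total
   fat-pixel area divided by the number of analyzed slices (mm²/slice).

### Why the ring is 2-D

The area is reported per slice and slice thickness (5 mm) is half the ring
width (10 mm); a 3-D dilation would smear the ring across slices whose
in-plane anatomy differs, and the through-plane distance would be
quantized to whole slices anyway. The in-plane ring keeps the geometry
exact at the stated resolution.

### Ring origin and what the mask delineates

On contrast CT a threshold segmentation delineates the blood pool, not the
outer wall. The package therefore measures the ring from the segmented
(lumen) boundary outward, and the phantom generator records its
ground-truth mask as the lumen disc, rendering the wall as a thin
soft-tissue annulus *inside* the ring, where the HU window excludes it.
This keeps the chain segmentation → ring → window exactly invertible on
phantoms while representing the realistic ambiguity that wall tissue sits
between vessel and fat.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| ring distance | 10 | mm | the perivascular reach used clinically |
| fat window | [−190, 0] | HU | wide fat range chosen for inflamed PVAT; closed interval |
| analyzed extent | 50 | mm | ascending aorta up to 5 cm distal to the root |
| lumen threshold | 150 | HU | below contrast blood (~300 HU), above soft tissue |
| radius gate | 10–25 | mm | adult ascending-aorta calibre |
| circularity gate | 0.8 | — | rejects crescents/branching structures |
| ROC orientation | higher = positive | — | inflamed fat is less negative |
| bootstrap | 2 000 reps, stratified, percentile | — | see below |

## Phantom generator

Each slice is a concentric structure: lumen disc (300 HU), wall annulus
(40 HU, 2 mm), then a perivascular region in which a seeded random
fraction (default 0.4) of the pixels within 10 mm of the lumen is fat and
the rest soft tissue (50 HU); everything further out is air (−1000 HU).
Fat HU values are Normal(mean, sd) truncated to the *open* interval
(−190, 0), so no ground-truth fat pixel can ever be excluded by the
window — this is what makes noiseless recovery exact rather than
approximate. Additive Gaussian noise (default 5 HU) is applied last, and
voxels are clipped to the valid HU range. Defaults (0.7 mm pixels, 5 mm
slices, 15 mm lumen, fat fraction 0.4 → ~410 mm²/slice, fat mean −62 HU)
emulate the imaging conditions and the control-group values of the
clinical cohort the package models.

The phantom is deliberately minimal: no thoracic anatomy, no
beam-hardening or correlated scanner noise, and fat placed uniformly at
random rather than in contiguous depots. Passing phantom tests therefore
demonstrates the *geometry and arithmetic* of the pipeline, not clinical
segmentation robustness; the published 94.4% detection rate on patient CT
is a property of the trained CNN and real anatomy and is not reproducible
here.

## Cohort simulator and the study-level statistics

Only group-level summaries of the clinical cohort are published, so the
simulator draws per-patient AA-FAI values as independent Gaussians at the
printed mean ± SD and sample sizes (159 / 36 / 9). Normality is the
minimal assumption consistent with the printed data; every simulation
tolerance inherits it. A single master seed expands through
`SeedSequence.spawn` into independent per-group and per-replicate streams.

`reproduce_study_roc` draws fresh cohorts per replicate and records, per
replicate, the empirical AUC, the Youden-optimal cutoff, and the
sensitivity/specificity at a fixed operating point (default −55.3 HU).
Replicate means over ≥500 cohorts are the quantities compared against the
published 0.74 / 0.73 AUCs, 0.61 / 0.81 operating characteristics, and
−55.3 HU cutoff. The Youden cutoff of a ~200-sample empirical ROC is a
noisy, slightly biased estimator, so its replicate mean (≈ −54.4 HU) sits
near, not exactly on, the population-optimal value; the sensitivity at the
fixed cutoff is likewise the plug-in Gaussian tail (≈ 0.57 for the Marfan
group), consistent with the published 0.61 to within sampling error of a
36-patient group.

## Numerical and statistical choices

- **ROC construction.** Candidate cutoffs at midpoints between adjacent
  distinct scores plus ±∞; sensitivity = fraction of positives ≥ cutoff.
  The curve points are sorted lexicographically by (FPR, TPR) so the
  trapezoidal area equals the Mann–Whitney pair statistic exactly,
  including tie credit of ½ (verified against exhaustive pair counting
  and scikit-learn in the tests). Youden ties resolve to the smallest
  cutoff.
- **AUC confidence interval.** No interval method is prescribed by the
  analyses this package mirrors; the package uses a seeded, stratified
  (cases and controls resampled separately) percentile bootstrap with
  2,000 replicates. This is a documented substitute, not a claim of
  method identity; its coverage of the true binormal AUC is checked by
  simulation in the test suite.
- **Welch from summaries.** The summary-level Welch statistic and
  Satterthwaite degrees of freedom are computed directly from mean/SD/n
  (cross-checked against scipy on raw data). Note that the published
  statin-use comparison (P = 0.039) is not recovered by Welch's formula
  applied to its printed summaries (≈ 0.02); the test used for that panel
  was likely a normality-dependent nonparametric fallback, so the package
  asserts only the formula, not that P value.
- **Rescale fallback.** DICOM slices missing rescale tags get the CT
  convention slope 1 / intercept −1024 and a `default_rescale` flag —
  flagged, never silent.
- **Degenerate inputs.** Zero fat pixels → `no_fat` flag, AA-FAI reported
  as missing and excluded from cohort statistics. Empty mask slices are
  skipped with a flag. A ring touching the image border sets
  `border_clipped` but is still measured.
- **Boundary semantics.** All clinical cutoffs are strict as printed:
  SBP 140 or DBP 90 exactly → not hypertensive; eGFR 60.0 → no CKD;
  diameter 35.0 mm → mild dilatation, 50.0 mm → severe. The fat window is
  closed: −190 HU and 0 HU are both fat.

## Problem sizes

Phantom tests use 96–160 px grids with 2–4 slices at 0.7 × 0.7 × 5 mm;
geometry oracles run on ≤ 32 px grids where an all-pairs distance scan is
exact and fast; replication statistics use 500 replicate cohorts of the
published 204-patient structure. These sizes give the oracles full
coverage (the ring construction is resolution-independent) and keep
simulation standard errors an order of magnitude below the comparison
tolerances.

## Known limitations

- The classical detector assumes contrast-enhanced acquisition and a
  roughly circular cross-section; it is not a substitute for learned
  segmentation on real anatomy (pulmonary artery, SVC and aortic arch
  neighbors are absent from phantoms).
- No exclusion of non-fat anatomy beyond the HU window: contiguous
  mediastinal fat, airways or adjacent vessels inside the 10 mm ring are
  treated like any other pixel, as in the procedure the package models;
  users with real data can pass exclusion-aware external masks.
- The Gaussian cohort model ignores any skewness, covariate structure or
  measurement error in the real AA-FAI distributions; replicate means are
  faithful to the printed summaries, not to unpublished patient-level
  features.
- Anchor selection uses the first detected slice, not an anatomical root
  localization; on volumes that include the arch above the root, an
  explicit `anchor_index` should be supplied.
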