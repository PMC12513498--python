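# aafai — perivascular fat attenuation of the ascending aorta from CT

Inflamed perivascular adipose tissue (PVAT) loses lipid and takes up water,
which shifts its CT attenuation toward zero. The **fat attenuation index of
the ascending aorta (AA-FAI)** exploits this: segment the vessel on
contrast-enhanced chest CT, take every pixel within **10 mm** of the vessel
whose attenuation falls in the fat window **[−190, 0] HU** (the *ct-PVAT*),
and report their pooled mean attenuation,

```
AA-FAI = ( Σ_fat-pixels HU ) / N_fat        [HU]
ct-PVAT area = N_fat · pixel_area / N_slices  [mm²/slice]
```

where the sum runs over all analyzed slices (up to 5 cm of vessel, ~10
slices at 5 mm thickness). A higher (less negative) AA-FAI indicates
adipose inflammation; in hereditary connective tissue disorders (HCTD:
Marfan and Loeys–Dietz syndromes) it discriminates patients from controls
with AUC ≈ 0.73–0.74 and a Youden-optimal cutoff near −55.3 HU.

The package is aimed at imaging researchers who want a tested, transparent
reference implementation of this pipeline: it provides the geometry
(anisotropic-spacing Euclidean ring construction), the HU windowing, a
classical aorta detector plus an external-mask interface for CNN output,
the clinical metrics used alongside (Mosteller BSA, aortic size index,
comorbidity/dilatation classification), the cohort statistics (Welch,
ANOVA/Tukey, Pearson, ROC with bootstrap CI and Youden cutoff), and a
synthetic phantom/cohort generator so every stage is verifiable without
patient data.

## Worked example

```python
from aafai import PhantomSpec, make_phantom, detect_aorta_classical, select_extent, analyze

spec = PhantomSpec(noise_sd=0.0, fat_hu_mean=-62.0, fat_hu_sd=8.5, seed=7)
volume, _, truth = make_phantom(spec)
mask, report = detect_aorta_classical(volume)
result = analyze(volume, mask, slice_range=select_extent(mask, volume))
```

prints (see `examples/01_phantom_fai.py`):

```
detection success: True (100% of slices)
AA-FAI   pipeline  -62.0184 HU   truth  -62.0184 HU
ct-PVAT  pipeline    410.62 mm²/slice   truth    410.62
fat pixels: 8380 (truth 8380)
```

On a noiseless phantom the pipeline recovers the generator's ground truth
*exactly* — the fat mask is identical pixel-for-pixel, so the pooled mean
and the per-slice area match to the last bit. An AA-FAI of −62 HU is a
typical non-HCTD value; inflamed PVAT in Marfan patients averages −52.9 HU.

The other example scripts cover ROC analysis on a simulated cohort
(`02_cohort_roc.py`), derived clinical metrics (`03_clinical_metrics.py`)
and full replication of the study-level statistics
(`04_study_replication.py`).

A thin CLI mirrors the library for shell use: `aafai phantom`, `aafai
cohort`, `aafai segment`, `aafai fai`, `aafai roc`, and `aafai run
--config run.toml` for a full manifest-driven run with provenance logging.

## Scope

The study's trained Mask R-CNN segmentation is not bundled (no weights or
annotations are published); the classical detector stands in on phantoms
and clean contrast CT, and CNN output can be supplied as NIfTI or polygon
masks. Mouse experiments, histology, and propensity-score matching from
the source study are out of scope. See `docs/methods.md` for the model,
parameter, and design details.
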