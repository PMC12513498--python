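"""Build a vessel phantom and recover its perivascular fat exactly.

The phantom embeds a contrast-filled aorta in a perivascular region where a
known subset of pixels is fat with known attenuation.  Running the full
pipeline (detect → 10 mm ring → −190..0 HU window → pooled mean) on the
noiseless phantom must return the ground-truth fat mean and area exactly;
with noise the error shrinks as 1/√(number of fat pixels).
"""

from aafai import PhantomSpec, analyze, detect_aorta_classical, make_phantom, select_extent

spec = PhantomSpec(noise_sd=0.0, fat_hu_mean=-62.0, fat_hu_sd=8.5, seed=7)
volume, _, truth = make_phantom(spec)

mask, report = detect_aorta_classical(volume)
extent = select_extent(mask, volume)
result = analyze(volume, mask, slice_range=extent)

print(f"detection success: {report.success} ({report.fraction_detected:.0%} of slices)")
print(f"AA-FAI   pipeline {result.aa_fai:9.4f} HU   truth {truth.fat_mean_hu:9.4f} HU")
print(f"ct-PVAT  pipeline {result.ct_pvat_area:9.2f} mm²/slice   truth {truth.fat_area_mm2_per_slice:9.2f}")
print(f"fat pixels: {result.n_fat_pixels} (truth {truth.n_fat_pixels})")
# AA-FAI is the pooled mean HU of all fat pixels within 10 mm of the vessel;
# on a noiseless phantom the two columns agree exactly.
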