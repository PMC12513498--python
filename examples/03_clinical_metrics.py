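"""Derived clinical quantities for one patient record.

Shows the Mosteller body surface area, the aortic size index (diameter
normalized by BSA), comorbidity classification under the strict study
cutoffs, and the aortic dilatation category.
"""

from aafai import PatientRecord

rec = PatientRecord(
    id="demo", group="non_HCTD", height=170, weight=72, aortic_diameter=45,
    sbp=145, dbp=80, hba1c=6.0, ldl=120, egfr=58, uric_acid=6.0,
    antihypertensive=False, antidiabetic=False, lipid_lowering=True,
    urate_lowering=False,
).derive()

print(f"BSA (Mosteller)     {rec.bsa:.4f} m²")
print(f"aortic size index   {rec.asi:.2f} mm/m²")
print(f"dilatation          {rec.dilatation}  (none <35 mm, severe ≥50 mm)")
for name, flag in rec.comorbidities.items():
    print(f"  {name:14s} {flag}")
# hypertension is True from SBP 145 > 140; dyslipidemia from medication use
# despite normal LDL; CKD from eGFR 58 < 60.
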