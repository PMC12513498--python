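"""Derived clinical quantities: BSA, aortic size index, comorbidity and
dilatation classification.

All cutoffs follow the study definitions literally, with strict
inequalities: hypertension is SBP > 140 mmHg or DBP > 90 mmHg or
antihypertensive use; diabetes HbA1c > 6.5 % (NGSP) or antidiabetic use;
dyslipidemia LDL > 140 mg/dL or lipid-lowering use; CKD eGFR < 60
mL/min/1.73 m²; hyperuricemia uric acid > 7.0 mg/dL or urate-lowering use.
Ascending-aortic dilatation: none < 35 mm, severe ≥ 50 mm (the surgical
threshold), mild in between.  A missing covariate makes the corresponding
flag undetermined (``None``), never silently False.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional


@dataclass
class PatientRecord:
    """One clinical row; derived fields stay ``None`` until computed."""

    id: str
    group: Optional[str] = None          # non_HCTD | MFS | LDS
    height: Optional[float] = None       # cm
    weight: Optional[float] = None       # kg
    aortic_diameter: Optional[float] = None  # mm
    sbp: Optional[float] = None          # mmHg
    dbp: Optional[float] = None          # mmHg
    hba1c: Optional[float] = None        # % (NGSP)
    ldl: Optional[float] = None          # mg/dL
    egfr: Optional[float] = None         # mL/min/1.73 m²
    uric_acid: Optional[float] = None    # mg/dL
    antihypertensive: Optional[bool] = None
    antidiabetic: Optional[bool] = None
    lipid_lowering: Optional[bool] = None
    urate_lowering: Optional[bool] = None
    statin: Optional[bool] = None
    aa_fai: Optional[float] = None       # HU
    # derived
    bsa: Optional[float] = None          # m²
    asi: Optional[float] = None          # mm/m²
    comorbidities: Optional[dict] = None
    dilatation: Optional[str] = None

    def derive(self) -> "PatientRecord":
        """Fill every derivable field in place (idempotent)."""
        if self.height is not None and self.weight is not None:
            self.bsa = bsa_mosteller(self.height, self.weight)
        if self.aortic_diameter is not None and self.bsa is not None:
            self.asi = aortic_size_index(self.aortic_diameter, self.bsa)
        self.comorbidities = classify_comorbidities(self)
        if self.aortic_diameter is not None:
            self.dilatation = classify_dilatation(self.aortic_diameter)
        return self


def bsa_mosteller(height: float, weight: float) -> float:
    """Body surface area (m²) by the Mosteller formula √(h·w/3600)."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height * weight / 3600.0)


def aortic_size_index(diameter: float, bsa: float) -> float:
    """Aortic size index (mm/m²): diameter divided by body surface area."""
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    return diameter / bsa


def _defined_or(*parts: Optional[bool]) -> Optional[bool]:
    """Disjunction with undetermined propagation: any True wins; a missing
    part only makes the result undetermined when no part is True."""
    known = [p for p in parts if p is not None]
    if any(known):
        return True
    if len(known) == len(parts):
        return False
    return None


def classify_comorbidities(record: PatientRecord) -> dict:
    """Comorbidity flags with strict printed cutoffs; missing → ``None``."""
    sbp_high = None if record.sbp is None else record.sbp > 140
    dbp_high = None if record.dbp is None else record.dbp > 90
    hba1c_high = None if record.hba1c is None else record.hba1c > 6.5
    ldl_high = None if record.ldl is None else record.ldl > 140
    egfr_low = None if record.egfr is None else record.egfr < 60
    ua_high = None if record.uric_acid is None else record.uric_acid > 7.0
    return {
        "hypertension": _defined_or(sbp_high, dbp_high, record.antihypertensive),
        "diabetes": _defined_or(hba1c_high, record.antidiabetic),
        "dyslipidemia": _defined_or(ldl_high, record.lipid_lowering),
        "ckd": egfr_low,
        "hyperuricemia": _defined_or(ua_high, record.urate_lowering),
    }


def classify_dilatation(diameter: float) -> str:
    """Ascending-aorta dilatation category: none < 35 mm, severe ≥ 50 mm."""
    if diameter <= 0:
        raise ValueError("aortic diameter must be positive")
    if diameter < 35:
        return "none"
    if diameter >= 50:
        return "severe"
    return "mild"
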