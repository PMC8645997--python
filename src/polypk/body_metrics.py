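"""Body-size descriptors and creatinine-clearance variants.

Obese patients are dosed by weight, but which weight matters: total body
weight (TBW) over-doses, ideal body weight (IBW) under-doses, and adjusted
body weight (ABW = IBW + 0.4·(TBW − IBW)) interpolates between them.  These
descriptors, together with Cockcroft-Gault creatinine clearance computed
with each weight in turn, are the candidate covariates of the population
model and the scaling weights of the simulated regimens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PatientCovariates",
    "DerivedBodyMetrics",
    "ideal_body_weight",
    "adjusted_body_weight",
    "body_mass_index",
    "cockcroft_gault",
    "derive_metrics",
    "append_derived_columns",
]

#: µmol/L per mg/dL of creatinine (molar mass conversion).
SCR_UMOL_PER_MGDL = 88.4


@dataclass(frozen=True)
class PatientCovariates:
    """Raw per-patient covariates as collected from records.

    sex is "male"/"female"; scr is serum creatinine in µmol/L; gfr is an
    externally supplied estimate (mL/min·1.73 m²) and is never computed here.
    """

    sex: str
    age: float
    height: float  # cm
    tbw: float  # kg
    scr: float  # µmol/L
    sofa: int = 0
    gfr: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 18:
            raise ValueError("age must be >= 18 years")
        if self.height <= 0 or self.tbw <= 0 or self.scr <= 0:
            raise ValueError("height, tbw and scr must be positive")


@dataclass(frozen=True)
class DerivedBodyMetrics:
    bmi: float  # kg/m²
    ibw: float  # kg
    abw: float  # kg
    crcl_tbw: float  # mL/min
    crcl_abw: float  # mL/min
    crcl_ibw: float  # mL/min


def ideal_body_weight(sex: str, height: float) -> float:
    """Devine ideal body weight (kg) from sex and height in cm.

    IBW = (height/2.54 − 60) × 2.3 + 50 (male) or 45.5 (female).  Heights
    below 152.4 cm produce a negative bracket term; the formula value is
    returned unclamped with a warning, since the obese cohort this package
    models never reaches that range.
    """
    height = float(height)
    if height <= 0:
        raise ValueError("height must be positive (cm)")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    inches_over_5ft = height / 2.54 - 60.0
    if inches_over_5ft < 0:
        warnings.warn(
            f"height {height} cm is below 152.4 cm; ideal body weight formula "
            "extrapolates below its intended range",
            stacklevel=2,
        )
    base = 50.0 if sex == "male" else 45.5
    return inches_over_5ft * 2.3 + base


def adjusted_body_weight(ibw: float, tbw: float) -> float:
    """ABW = IBW + 0.4·(TBW − IBW), the usual dosing-weight compromise."""
    if ibw <= 0 or tbw <= 0:
        raise ValueError("ibw and tbw must be positive (kg)")
    return ibw + 0.4 * (tbw - ibw)


def body_mass_index(tbw: float, height: float) -> float:
    """BMI (kg/m²) from weight in kg and height in cm."""
    if height <= 0 or tbw <= 0:
        raise ValueError("tbw and height must be positive")
    return tbw / (height / 100.0) ** 2


def cockcroft_gault(sex: str, age: float, weight: float, scr: float) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min).

    CrCL = (140 − age) · weight / (72 · SCr[mg/dL]), × 0.85 for females.
    ``scr`` is taken in µmol/L (as reported clinically) and converted by
    dividing by 88.4.  The ``weight`` argument selects the variant: pass
    TBW, ABW or IBW for total, adjusted or ideal CrCL.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if age <= 0 or age >= 130:
        raise ValueError("age must be in (0, 130) years")
    if weight <= 0:
        raise ValueError("weight must be positive (kg)")
    if scr <= 0:
        raise ValueError("serum creatinine must be positive (µmol/L)")
    scr_mgdl = scr / SCR_UMOL_PER_MGDL
    crcl = (140.0 - age) * weight / (72.0 * scr_mgdl)
    if sex == "female":
        crcl *= 0.85
    return crcl


def derive_metrics(cov: PatientCovariates) -> DerivedBodyMetrics:
    """All derived body metrics and CrCL variants for one patient."""
    ibw = ideal_body_weight(cov.sex, cov.height)
    abw = adjusted_body_weight(ibw, cov.tbw)
    return DerivedBodyMetrics(
        bmi=body_mass_index(cov.tbw, cov.height),
        ibw=ibw,
        abw=abw,
        crcl_tbw=cockcroft_gault(cov.sex, cov.age, cov.tbw, cov.scr),
        crcl_abw=cockcroft_gault(cov.sex, cov.age, abw, cov.scr),
        crcl_ibw=cockcroft_gault(cov.sex, cov.age, ibw, cov.scr),
    )


def append_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Append BMI/IBW/ABW/CrCL columns to a covariate table.

    Expects columns SEX (0=male, 1=female), AGE, HT, TBW, SCR.  Returns a
    copy with BMI, IBW, ABW, CRCL_TBW, CRCL_ABW, CRCL_IBW added.
    """
    required = {"SEX", "AGE", "HT", "TBW", "SCR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    out = df.copy()
    sex = np.where(out["SEX"].to_numpy() == 0, "male", "female")
    rows = [
        derive_metrics(
            PatientCovariates(
                sex=s,
                age=float(a),
                height=float(h),
                tbw=float(w),
                scr=float(c),
            )
        )
        for s, a, h, w, c in zip(sex, out["AGE"], out["HT"], out["TBW"], out["SCR"])
    ]
    out["BMI"] = [r.bmi for r in rows]
    out["IBW"] = [r.ibw for r in rows]
    out["ABW"] = [r.abw for r in rows]
    out["CRCL_TBW"] = [r.crcl_tbw for r in rows]
    out["CRCL_ABW"] = [r.crcl_abw for r in rows]
    out["CRCL_IBW"] = [r.crcl_ibw for r in rows]
    return out
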