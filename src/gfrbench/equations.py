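"""GFR estimating equations and anthropometric helpers.

Implements the six serum-marker prediction equations commonly validated
against exogenous-tracer measured GFR:

* the original 7-variable MDRD equation (creatinine, urea nitrogen, albumin),
* the abbreviated 4-variable MDRD and its IDMS re-expressed form,
* the 2009 CKD-EPI creatinine equation,
* the 2012 CKD-EPI cystatin C and combined creatinine–cystatin C equations,

plus Du Bois body surface area, BMI, BSA standardisation of a raw clearance,
and the unit conversions needed to feed SI laboratory values into the
equations (which expect creatinine and urea nitrogen in mg/dl).

All equation functions are vectorised over numpy arrays; sex is passed as
the strings ``"male"``/``"female"`` (scalar or array). Outputs are eGFR in
ml/min per 1.73 m² body surface area, at full floating precision — rounding
is left to report writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "EquationId",
    "PatientRecord",
    "MissingAnalyteError",
    "egfr_mdrd7",
    "egfr_amdrd",
    "egfr_re_amdrd",
    "egfr_ckd_epi_cr",
    "egfr_ckd_epi_cys",
    "egfr_ckd_epi_cr_cys",
    "bsa_dubois",
    "bmi",
    "standardize_gfr",
    "destandardize_gfr",
    "convert_units",
    "estimate_table",
    "read_patients",
    "write_patients",
    "PATIENT_COLUMNS",
]


class MissingAnalyteError(ValueError):
    """A required serum analyte is absent for this equation."""

    def __init__(self, analyte: str):
        self.analyte = analyte
        super().__init__(f"missing required analyte: {analyte}")


class EquationId(str, Enum):
    """The six estimating equations, in display order."""

    MDRD7 = "MDRD7"
    AMDRD = "AMDRD"
    RE_AMDRD = "RE_AMDRD"
    CKD_EPI_CR = "CKD_EPI_CR"
    CKD_EPI_CYS = "CKD_EPI_CYS"
    CKD_EPI_CR_CYS = "CKD_EPI_CR_CYS"

    @property
    def requires(self) -> tuple[str, ...]:
        """Analyte columns this equation needs beyond age/sex."""
        return _REQUIRES[self]


_REQUIRES = {
    EquationId.MDRD7: ("scr_mgdl", "bun_mgdl", "albumin_gdl"),
    EquationId.AMDRD: ("scr_mgdl",),
    EquationId.RE_AMDRD: ("scr_mgdl",),
    EquationId.CKD_EPI_CR: ("scr_mgdl",),
    EquationId.CKD_EPI_CYS: ("scys_mgl",),
    EquationId.CKD_EPI_CR_CYS: ("scr_mgdl", "scys_mgl"),
}

# Canonical delimited-text schema for patient records.
PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "race_black",
    "scr_mgdl",
    "scys_mgl",
    "bun_mgdl",
    "albumin_gdl",
    "weight_kg",
    "height_cm",
    "mgfr_raw_mlmin",
    "mgfr_std",
    "laterality",
    "duration_ge_3mo",
]


@dataclass
class PatientRecord:
    """One subject: demographics, serum markers, anthropometrics, measured GFR.

    ``mgfr_raw`` is the tracer clearance in ml/min before body-surface-area
    indexing; ``mgfr_std`` is indexed to 1.73 m². Either may be omitted for
    pure estimation use; at least one must be present for validation.
    """

    patient_id: str
    age: float
    sex: str
    weight: float
    height: float
    scr: float
    race_black: bool = False
    scys: Optional[float] = None
    bun: Optional[float] = None
    albumin: Optional[float] = None
    mgfr_raw: Optional[float] = None
    mgfr_std: Optional[float] = None
    laterality: Optional[str] = None
    duration_ge_3mo: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 18:
            raise ValueError(f"age must be >= 18 years, got {self.age}")
        for name in ("scr", "weight", "height"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("scys", "bun", "albumin", "mgfr_raw", "mgfr_std"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when present, got {v}")
        if self.laterality not in (None, "unilateral", "bilateral"):
            raise ValueError(f"invalid laterality: {self.laterality!r}")

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "age": self.age,
            "sex": self.sex,
            "race_black": self.race_black,
            "scr_mgdl": self.scr,
            "scys_mgl": self.scys,
            "bun_mgdl": self.bun,
            "albumin_gdl": self.albumin,
            "weight_kg": self.weight,
            "height_cm": self.height,
            "mgfr_raw_mlmin": self.mgfr_raw,
            "mgfr_std": self.mgfr_std,
            "laterality": self.laterality,
            "duration_ge_3mo": self.duration_ge_3mo,
        }


def _female_mask(sex) -> np.ndarray:
    sex = np.asarray(sex)
    valid = np.isin(sex, ["male", "female"])
    if not np.all(valid):
        bad = np.unique(sex[~valid])
        raise ValueError(f"sex must be 'male' or 'female', got {bad.tolist()}")
    return sex == "female"


def _require_positive(name: str, value) -> np.ndarray:
    if value is None:
        raise MissingAnalyteError(name)
    arr = np.asarray(value, dtype=float)
    if np.any(np.isnan(arr)):
        raise MissingAnalyteError(name)
    if np.any(arr <= 0):
        raise ValueError(f"{name} must be positive")
    return arr


def _check_age(age) -> np.ndarray:
    arr = np.asarray(age, dtype=float)
    if np.any(np.isnan(arr)) or np.any(arr < 18):
        raise ValueError("age must be >= 18 years")
    return arr


def egfr_mdrd7(scr, age, sex, race_black=False, bun=None, albumin=None):
    """Original 7-variable MDRD equation.

    170 · Scr^−0.999 · Age^−0.176 · BUN^−0.170 · Alb^0.318
    × 0.762 if female × 1.180 if black; Scr and BUN in mg/dl, Alb in g/dl.
    """
    scr = _require_positive("scr", scr)
    bun = _require_positive("bun", bun)
    albumin = _require_positive("albumin", albumin)
    age = _check_age(age)
    female = _female_mask(sex)
    out = (
        170.0
        * scr ** -0.999
        * age ** -0.176
        * bun ** -0.170
        * albumin ** 0.318
    )
    out = out * np.where(female, 0.762, 1.0) * np.where(np.asarray(race_black), 1.180, 1.0)
    return out[()] if out.ndim == 0 else out


def egfr_amdrd(scr, age, sex, race_black=False):
    """Abbreviated (4-variable) MDRD: 186 · Scr^−1.154 · Age^−0.203."""
    return _mdrd4(186.0, scr, age, sex, race_black)


def egfr_re_amdrd(scr, age, sex, race_black=False):
    """IDMS re-expressed abbreviated MDRD: 175 · Scr^−1.154 · Age^−0.203."""
    return _mdrd4(175.0, scr, age, sex, race_black)


def _mdrd4(constant, scr, age, sex, race_black):
    scr = _require_positive("scr", scr)
    age = _check_age(age)
    female = _female_mask(sex)
    out = constant * scr ** -1.154 * age ** -0.203
    out = out * np.where(female, 0.742, 1.0) * np.where(np.asarray(race_black), 1.212, 1.0)
    return out[()] if out.ndim == 0 else out


def egfr_ckd_epi_cr(scr, age, sex, race_black=False):
    """2009 CKD-EPI creatinine equation.

    Sex-specific piecewise: female 144 · (Scr/0.7)^e · 0.993^Age with
    e = −0.329 for Scr ≤ 0.7 else −1.209; male 141 · (Scr/0.9)^e with
    e = −0.411 for Scr ≤ 0.9 else −1.209; ×1.159 if black.
    """
    scr = _require_positive("scr", scr)
    age = _check_age(age)
    female = _female_mask(sex)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    const = np.where(female, 144.0, 141.0)
    expo = np.where(scr <= kappa, alpha, -1.209)
    out = const * (scr / kappa) ** expo * 0.993 ** age
    out = out * np.where(np.asarray(race_black), 1.159, 1.0)
    return out[()] if out.ndim == 0 else out


def egfr_ckd_epi_cys(scys, age, sex):
    """2012 CKD-EPI cystatin C equation.

    133 · (Scys/0.8)^e · 0.996^Age, e = −0.499 for Scys ≤ 0.8 else −1.328;
    ×0.932 if female.
    """
    scys = _require_positive("scys", scys)
    age = _check_age(age)
    female = _female_mask(sex)
    expo = np.where(scys <= 0.8, -0.499, -1.328)
    out = 133.0 * (scys / 0.8) ** expo * 0.996 ** age
    out = out * np.where(female, 0.932, 1.0)
    return out[()] if out.ndim == 0 else out


def egfr_ckd_epi_cr_cys(scr, scys, age, sex, race_black=False):
    """2012 CKD-EPI combined creatinine–cystatin C equation.

    Sex-specific constant (130 female / 135 male) and creatinine term
    ((Scr/0.7)^{−0.248/−0.601} female at threshold 0.7;
    (Scr/0.9)^{−0.207/−0.601} male at threshold 0.9), shared cystatin term
    (Scys/0.8)^{−0.375/−0.711}, 0.995^Age, ×1.08 if black.
    """
    scr = _require_positive("scr", scr)
    scys = _require_positive("scys", scys)
    age = _check_age(age)
    female = _female_mask(sex)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.248, -0.207)
    const = np.where(female, 130.0, 135.0)
    cr_expo = np.where(scr <= kappa, alpha, -0.601)
    cys_expo = np.where(scys <= 0.8, -0.375, -0.711)
    out = (
        const
        * (scr / kappa) ** cr_expo
        * (scys / 0.8) ** cys_expo
        * 0.995 ** age
    )
    out = out * np.where(np.asarray(race_black), 1.08, 1.0)
    return out[()] if out.ndim == 0 else out


def bsa_dubois(weight, height):
    """Du Bois body surface area: 0.007184 · weight^0.425 · height^0.725.

    weight in kg, height in cm; returns m².
    """
    weight = _require_positive("weight", weight)
    height = _require_positive("height", height)
    out = 0.007184 * weight ** 0.425 * height ** 0.725
    return out[()] if out.ndim == 0 else out


def bmi(weight, height):
    """Body mass index: weight (kg) / height (m)², height given in cm."""
    weight = _require_positive("weight", weight)
    height = _require_positive("height", height)
    out = weight / (height / 100.0) ** 2
    return out[()] if out.ndim == 0 else out


def standardize_gfr(gfr_raw, bsa):
    """Index a raw clearance (ml/min) to 1.73 m²: gfr_raw · 1.73 / BSA."""
    bsa = _require_positive("bsa", bsa)
    out = np.asarray(gfr_raw, dtype=float) * 1.73 / bsa
    return out[()] if out.ndim == 0 else out


def destandardize_gfr(gfr_std, bsa):
    """Inverse of :func:`standardize_gfr`: gfr_std · BSA / 1.73."""
    bsa = _require_positive("bsa", bsa)
    out = np.asarray(gfr_std, dtype=float) * bsa / 1.73
    return out[()] if out.ndim == 0 else out


# Exact multiplicative conversions between supported laboratory units.
# Creatinine: 1 mg/dl = 88.4 umol/l. Urea: 1 mmol/l = 6.006 mg/dl.
# Urea nitrogen carries 28/60 of the urea mass (two N atoms of CH4N2O).
_CONVERSIONS = {
    ("creatinine_umol_l", "creatinine_mg_dl"): 1.0 / 88.4,
    ("creatinine_mg_dl", "creatinine_umol_l"): 88.4,
    ("urea_mmol_l", "urea_mg_dl"): 6.006,
    ("urea_mg_dl", "urea_mmol_l"): 1.0 / 6.006,
    ("urea_mg_dl", "urea_nitrogen_mg_dl"): 28.0 / 60.0,
    ("urea_nitrogen_mg_dl", "urea_mg_dl"): 60.0 / 28.0,
}


def convert_units(value, from_unit: str, to_unit: str):
    """Convert between supported laboratory units.

    Supported: creatinine μmol/l ↔ mg/dl, urea mmol/l ↔ mg/dl, and
    urea mg/dl ↔ urea-nitrogen mg/dl. Unit names are lowercase with
    underscores, e.g. ``"creatinine_umol_l"``.
    """
    if from_unit == to_unit and from_unit in {u for pair in _CONVERSIONS for u in pair}:
        return value
    try:
        factor = _CONVERSIONS[(from_unit, to_unit)]
    except KeyError:
        raise ValueError(
            f"unsupported unit conversion: {from_unit!r} -> {to_unit!r}"
        ) from None
    out = np.asarray(value, dtype=float) * factor
    return out[()] if out.ndim == 0 else out


def estimate_table(data: pd.DataFrame) -> pd.DataFrame:
    """Evaluate all six equations on a cohort table.

    Parameters
    ----------
    data : DataFrame with the canonical patient columns (see
        ``PATIENT_COLUMNS``); ``scys_mgl``, ``bun_mgdl`` and ``albumin_gdl``
        may contain missing values.

    Returns
    -------
    DataFrame indexed like ``data``, one column per equation (the
    ``EquationId`` values), eGFR in ml/min/1.73 m². A cell is NaN exactly
    when a required analyte is missing for that patient.
    """
    for col in ("age", "sex", "scr_mgdl"):
        if col not in data.columns:
            raise ValueError(f"required column missing: {col}")
    n = len(data)
    age = data["age"].to_numpy(dtype=float)
    sex = data["sex"].to_numpy()
    black = (
        data["race_black"].fillna(False).to_numpy(dtype=bool)
        if "race_black" in data.columns
        else np.zeros(n, dtype=bool)
    )

    def col(name):
        if name in data.columns:
            return pd.to_numeric(data[name], errors="coerce").to_numpy(dtype=float)
        return np.full(n, np.nan)

    scr = col("scr_mgdl")
    scys = col("scys_mgl")
    bun = col("bun_mgdl")
    alb = col("albumin_gdl")

    out = pd.DataFrame(index=data.index)

    def fill(eq: EquationId, mask: np.ndarray, compute) -> None:
        vals = np.full(n, np.nan)
        if mask.any():
            vals[mask] = compute(mask)
        out[eq.value] = vals

    ok_scr = ~np.isnan(scr)
    ok_cys = ~np.isnan(scys)
    fill(
        EquationId.MDRD7,
        ok_scr & ~np.isnan(bun) & ~np.isnan(alb),
        lambda m: egfr_mdrd7(scr[m], age[m], sex[m], black[m], bun[m], alb[m]),
    )
    fill(EquationId.AMDRD, ok_scr, lambda m: egfr_amdrd(scr[m], age[m], sex[m], black[m]))
    fill(EquationId.RE_AMDRD, ok_scr, lambda m: egfr_re_amdrd(scr[m], age[m], sex[m], black[m]))
    fill(EquationId.CKD_EPI_CR, ok_scr, lambda m: egfr_ckd_epi_cr(scr[m], age[m], sex[m], black[m]))
    fill(EquationId.CKD_EPI_CYS, ok_cys, lambda m: egfr_ckd_epi_cys(scys[m], age[m], sex[m]))
    fill(
        EquationId.CKD_EPI_CR_CYS,
        ok_scr & ok_cys,
        lambda m: egfr_ckd_epi_cr_cys(scr[m], scys[m], age[m], sex[m], black[m]),
    )
    return out


def read_patients(path) -> pd.DataFrame:
    """Read a patient cohort from delimited text (comma-separated)."""
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "age", "sex", "scr_mgdl") if c not in df.columns]
    if missing:
        raise ValueError(f"patient file lacks required columns: {missing}")
    if "race_black" in df.columns:
        df["race_black"] = df["race_black"].astype("boolean").fillna(False).astype(bool)
    if "duration_ge_3mo" in df.columns:
        df["duration_ge_3mo"] = df["duration_ge_3mo"].astype("boolean")
    return df


def write_patients(df: pd.DataFrame, path) -> None:
    """Write a cohort in the canonical column order, empty cells for missing."""
    cols = [c for c in PATIENT_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)
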