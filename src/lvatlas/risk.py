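"""Guideline-based cardiovascular risk-factor definitions.

Five binary factors are derived from the clinical covariates:

* hypertension — on antihypertensive medication, or adjusted SBP/DBP at or
  above 140/90 mm Hg (130/80 mm Hg for diabetics). Measured pressures of
  treated participants are adjusted upward by a constant +15/+10 mm Hg
  before threshold comparison.
* diabetes — HbA1c above 48 mmol/mol (6.5%), insulin use, or a known
  diagnosis. Diabetes is resolved before hypertension because it lowers
  the blood-pressure thresholds.
* hypercholesterolaemia — severe LDL-C (>=190 mg/dL), or the very-high-risk
  combination LDL-C >= 100 mg/dL with age >= 65 and lipid-lowering
  medication.
* obesity — BMI above 30 kg/m^2 (strict).
* smoking — current or previous smoker.

Participants with none of the five factors form the no-risk reference
group. Missing covariates raise rather than impute (complete-case data are
assumed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingDataError
from .synthetic import FACTORS

__all__ = [
    "RiskProfile",
    "adjust_bp_for_medication",
    "determine_risk_profile",
    "add_risk_columns",
    "assign_groups",
]

BP_MED_SBP_OFFSET = 15.0
BP_MED_DBP_OFFSET = 10.0
HBA1C_THRESHOLD_MMOL_MOL = 48.0
HBA1C_THRESHOLD_PERCENT = 6.5
LDL_SEVERE_MG_DL = 190.0
LDL_VERY_HIGH_RISK_MG_DL = 100.0
VERY_HIGH_RISK_AGE = 65
BMI_OBESITY_KG_M2 = 30.0
FLAG_COLUMNS = list(FACTORS) + ["no_risk"]


@dataclass(frozen=True)
class RiskProfile:
    hypertension: bool
    diabetes: bool
    obesity: bool
    hypercholesterolaemia: bool
    smoking: bool

    @property
    def no_risk(self) -> bool:
        return not (
            self.hypertension
            or self.diabetes
            or self.obesity
            or self.hypercholesterolaemia
            or self.smoking
        )


def _require(df: pd.DataFrame, column: str) -> pd.Series:
    if column not in df.columns:
        raise MissingDataError(column)
    s = df[column]
    if s.isna().any():
        raise MissingDataError(column)
    return s


def adjust_bp_for_medication(sbp, dbp, on_medication):
    """Constant +15/+10 mm Hg adjustment for treated participants.

    Accepts scalars or arrays; NaN pressures raise."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.isnan(sbp).any() or np.isnan(dbp).any():
        raise MissingDataError("sbp_mmhg/dbp_mmhg")
    med = np.asarray(on_medication, dtype=bool)
    sbp_adj = sbp + BP_MED_SBP_OFFSET * med
    dbp_adj = dbp + BP_MED_DBP_OFFSET * med
    if sbp_adj.ndim == 0:
        return float(sbp_adj), float(dbp_adj)
    return sbp_adj, dbp_adj


def add_risk_columns(clinical: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the clinical table with the five factor flags,
    ``bmi`` and ``no_risk`` appended."""
    df = clinical.copy()
    age = _require(df, "age")
    height = _require(df, "height_cm")
    weight = _require(df, "weight_kg")
    insulin = _require(df, "insulin_med").astype(bool)
    diab_dx = _require(df, "diabetes_dx").astype(bool)
    anti_med = _require(df, "antihypertensive_med").astype(bool)
    lipid_med = _require(df, "lipid_med").astype(bool)
    smoking_status = _require(df, "smoking_status")

    if "hba1c_mmol_mol" in df.columns:
        hba1c_high = _require(df, "hba1c_mmol_mol") > HBA1C_THRESHOLD_MMOL_MOL
    elif "hba1c_percent" in df.columns:
        hba1c_high = _require(df, "hba1c_percent") > HBA1C_THRESHOLD_PERCENT
    else:
        raise MissingDataError("hba1c_mmol_mol")

    diabetes = hba1c_high | insulin | diab_dx

    sbp_adj, dbp_adj = adjust_bp_for_medication(
        _require(df, "sbp_mmhg").to_numpy(),
        _require(df, "dbp_mmhg").to_numpy(),
        anti_med.to_numpy(),
    )
    thr_s = np.where(diabetes, 130.0, 140.0)
    thr_d = np.where(diabetes, 80.0, 90.0)
    hypertension = anti_med.to_numpy() | (sbp_adj >= thr_s) | (dbp_adj >= thr_d)

    ldl = _require(df, "ldl_mg_dl")
    hyperchol = (ldl >= LDL_SEVERE_MG_DL) | (
        (ldl >= LDL_VERY_HIGH_RISK_MG_DL) & (age >= VERY_HIGH_RISK_AGE) & lipid_med
    )

    bmi = weight / (height / 100.0) ** 2
    obesity = bmi > BMI_OBESITY_KG_M2

    unknown = set(smoking_status.unique()) - {"never", "previous", "current"}
    if unknown:
        raise InvalidParameterError(f"unknown smoking_status values: {sorted(unknown)}")
    smoking = smoking_status.isin(["previous", "current"])

    df["bmi"] = bmi
    df["hypertension"] = np.asarray(hypertension, dtype=bool)
    df["diabetes"] = diabetes.to_numpy()
    df["obesity"] = obesity.to_numpy()
    df["hypercholesterolaemia"] = hyperchol.to_numpy()
    df["smoking"] = smoking.to_numpy()
    df["no_risk"] = ~df[list(FACTORS)].any(axis=1)
    return df


def determine_risk_profile(record: Mapping) -> RiskProfile:
    """Classify a single participant."""
    df = add_risk_columns(pd.DataFrame([dict(record)]))
    row = df.iloc[0]
    return RiskProfile(
        hypertension=bool(row["hypertension"]),
        diabetes=bool(row["diabetes"]),
        obesity=bool(row["obesity"]),
        hypercholesterolaemia=bool(row["hypercholesterolaemia"]),
        smoking=bool(row["smoking"]),
    )


def assign_groups(profiled: pd.DataFrame, factor: str) -> tuple[np.ndarray, np.ndarray]:
    """Positional indices of (risk group, no-risk group) for one factor.

    The risk group contains every case carrying the factor (regardless of
    other factors); the no-risk group contains cases with no factor at all;
    everyone else is excluded.
    """
    if factor not in FACTORS:
        raise InvalidParameterError(f"unknown risk factor: {factor!r}")
    for col in (factor, "no_risk"):
        if col not in profiled.columns:
            raise MissingDataError(col)
    risk = np.flatnonzero(profiled[factor].to_numpy(dtype=bool))
    norisk = np.flatnonzero(profiled["no_risk"].to_numpy(dtype=bool))
    if len(risk) == 0:
        import warnings

        warnings.warn(f"risk group for {factor!r} is empty", stacklevel=2)
    return risk, norisk
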