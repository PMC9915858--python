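"""Surrogate insulin-resistance indices and anthropometric ratios.

Implements the four IR surrogates evaluated against metabolic-syndrome
status — HOMA-IR, the triglyceride-glucose (TyG) index, the TG:HDL-C
ratio, and the lipid accumulation product (LAP) — together with BMI,
waist-hip and waist-height ratios and the Friedewald LDL derivation.

Definitions (fasting values; TG, FPG, HDL in mg/dL, insulin in μIU/mL):

    HOMA-IR = insulin × glucose(mmol/L) / 22.5
    TyG     = ln(TG × FPG) / 2
    TG:HDL  = TG / HDL
    LAP     = (waist − 65) × TG(mmol/L)   men
            = (waist − 58) × TG(mmol/L)   women

Glucose mg/dL → mmol/L uses the conventional divisor 18.0; triglyceride
mg/dL → mmol/L divides by 88.57.  LAP uses TG in mmol/L: with mg/dL the
index would be ~90× larger than its published reference ranges.  Both
factors are parameters of :class:`InsulinResistanceIndices`.

Scalar functions raise on domain errors; the vectorised transformer
propagates invalid inputs as missing (NaN), never as zeros.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import COHORT_COLUMNS

logger = logging.getLogger(__name__)

#: mg/dL per mmol/L for glucose (molar mass 180.16 ≈ 180).
GLUCOSE_MGDL_PER_MMOL = 18.0
#: mg/dL per mmol/L for triglycerides (average molar mass 885.7).
TG_MGDL_PER_MMOL = 88.57
#: Standard validity bound of the Friedewald formula.
FRIEDEWALD_TG_LIMIT = 400.0

#: Sex-specific waist offsets (cm) of the lipid accumulation product.
LAP_OFFSET = {"M": 65.0, "F": 58.0}

PANEL_COLUMNS = (
    "bmi",
    "whr",
    "whtr",
    "homa_ir",
    "tyg",
    "tg_hdl",
    "lap",
    "ldl_derived",
    "vldl_derived",
)


def glucose_mgdl_to_mmol(fpg: float, divisor: float = GLUCOSE_MGDL_PER_MMOL) -> float:
    """Convert fasting glucose from mg/dL to mmol/L."""
    if fpg < 0:
        raise ValueError(f"glucose must be non-negative, got {fpg}")
    return fpg / divisor

def homa_ir(insulin: float, fpg: float, glucose_divisor: float = GLUCOSE_MGDL_PER_MMOL) -> float:
    """Homeostasis model assessment of insulin resistance.

    ``insulin`` in μIU/mL, ``fpg`` in mg/dL (converted internally to mmol/L).
    """
    if insulin < 0:
        raise ValueError(f"insulin must be non-negative, got {insulin}")
    return insulin * glucose_mgdl_to_mmol(fpg, glucose_divisor) / 22.5

def tyg(tg: float, fpg: float) -> float:
    """Triglyceride-glucose index, ln(TG × FPG)/2, both in mg/dL."""
    if tg <= 0 or fpg <= 0:
        raise ValueError(f"TyG requires tg > 0 and fpg > 0, got tg={tg}, fpg={fpg}")
    return float(np.log(tg * fpg) / 2.0)

def tg_hdl_ratio(tg: float, hdl: float) -> float:
    """Triglyceride to HDL-cholesterol ratio, both in mg/dL."""
    if hdl <= 0:
        raise ValueError(f"TG:HDL requires hdl > 0, got {hdl}")
    return tg / hdl

def lap(sex: str, waist: float, tg: float, tg_mmol_factor: float = TG_MGDL_PER_MMOL) -> float:
    """Lipid accumulation product, (waist − offset) × TG in mmol/L.

    The waist offset is 65 cm for men and 58 cm for women.  A waist below
    the offset yields a negative LAP, which is returned as computed (with
    a warning) rather than clamped — clamping would distort ROC ranks.
    """
    if sex not in LAP_OFFSET:
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    if waist <= 0 or tg < 0:
        raise ValueError(f"LAP requires waist > 0 and tg >= 0, got {waist}, {tg}")
    value = (waist - LAP_OFFSET[sex]) * (tg / tg_mmol_factor)
    if value < 0:
        logger.warning("negative LAP (waist %.1f below offset %.0f)", waist, LAP_OFFSET[sex])
    return value

def bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) / height (m) squared; height given in cm."""
    if height <= 0:
        raise ValueError(f"height must be positive, got {height}")
    if weight < 0:
        raise ValueError(f"weight must be non-negative, got {weight}")
    return weight / (height / 100.0) ** 2

def ratios(waist: float, hip: float, height: float) -> tuple[float, float]:
    """Waist-hip and waist-height ratios (per subject, not ratio of means)."""
    if hip <= 0 or height <= 0:
        raise ValueError(f"hip and height must be positive, got hip={hip}, height={height}")
    return waist / hip, waist / height

def friedewald(total_chol: float, hdl: float, tg: float) -> tuple[float, float]:
    """Friedewald LDL derivation: VLDL = TG/5, LDL = TC − HDL − VLDL.

    Valid for TG < 400 mg/dL; above that LDL is returned as NaN (VLDL is
    still reported).
    """
    if min(total_chol, hdl, tg) < 0:
        raise ValueError("lipid inputs must be non-negative")
    vldl = tg / 5.0
    if tg >= FRIEDEWALD_TG_LIMIT:
        logger.warning("Friedewald invalid at TG %.0f mg/dL >= %.0f", tg, FRIEDEWALD_TG_LIMIT)
        return float("nan"), vldl
    return total_chol - hdl - vldl, vldl


class InsulinResistanceIndices(BaseEstimator, TransformerMixin):
    """Transformer deriving the full index panel from raw cohort columns.

    ``transform`` maps a cohort DataFrame (schema of
    :mod:`irindices.schema`) to a DataFrame with columns
    ``bmi, whr, whtr, homa_ir, tyg, tg_hdl, lap, ldl_derived, vldl_derived``
    aligned on the input index.  Missing or out-of-domain inputs propagate
    as NaN in the affected outputs only.  ``ldl_derived`` prefers a measured
    ``ldl_mgdl`` column when present, falling back to Friedewald.

    Parameters
    ----------
    glucose_divisor : float, default 18.0
        mg/dL per mmol/L for glucose in HOMA-IR.
    tg_mmol_factor : float, default 88.57
        mg/dL per mmol/L for triglycerides in LAP.
    prefer_measured_ldl : bool, default True
        Use a non-missing ``ldl_mgdl`` input over the Friedewald value.
    """

    def __init__(
        self,
        glucose_divisor: float = GLUCOSE_MGDL_PER_MMOL,
        tg_mmol_factor: float = TG_MGDL_PER_MMOL,
        prefer_measured_ldl: bool = True,
    ):
        self.glucose_divisor = glucose_divisor
        self.tg_mmol_factor = tg_mmol_factor
        self.prefer_measured_ldl = prefer_measured_ldl

    def fit(self, X: pd.DataFrame, y=None) -> "InsulinResistanceIndices":
        """No-op fit (the panel is a fixed derivation); validates columns."""
        self._check_columns(X)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _check_columns(X: pd.DataFrame) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"cohort frame missing column(s): {', '.join(missing)}")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_columns(X)
        with np.errstate(invalid="ignore", divide="ignore"):
            height_m = X["height_cm"].to_numpy(float) / 100.0
            weight = X["weight_kg"].to_numpy(float)
            waist = X["waist_cm"].to_numpy(float)
            hip = X["hip_cm"].to_numpy(float)
            fpg = X["fpg_mgdl"].to_numpy(float)
            ins = X["insulin_uiu_ml"].to_numpy(float)
            tc = X["tc_mgdl"].to_numpy(float)
            hdl = X["hdl_mgdl"].to_numpy(float)
            tgv = X["tg_mgdl"].to_numpy(float)
            male = X["sex"].to_numpy() == "M"

            out = pd.DataFrame(index=X.index)
            out["bmi"] = _guard(weight / height_m**2, height_m > 0)
            out["whr"] = _guard(waist / hip, hip > 0)
            out["whtr"] = _guard(waist / (height_m * 100.0), height_m > 0)
            out["homa_ir"] = _guard(
                ins * (fpg / self.glucose_divisor) / 22.5, (ins >= 0) & (fpg >= 0)
            )
            out["tyg"] = _guard(np.log(tgv * fpg) / 2.0, (tgv > 0) & (fpg > 0))
            out["tg_hdl"] = _guard(tgv / hdl, hdl > 0)
            offset = np.where(male, LAP_OFFSET["M"], LAP_OFFSET["F"])
            out["lap"] = _guard(
                (waist - offset) * tgv / self.tg_mmol_factor, (waist > 0) & (tgv >= 0)
            )
            n_neg = int(np.nansum(out["lap"].to_numpy() < 0))
            if n_neg:
                logger.warning("%d subject(s) with negative LAP (waist below offset)", n_neg)

            vldl = _guard(tgv / 5.0, tgv >= 0)
            ldl_fw = _guard(tc - hdl - vldl, (tc >= 0) & (hdl >= 0) & (tgv < FRIEDEWALD_TG_LIMIT))
            if self.prefer_measured_ldl and "ldl_mgdl" in X.columns:
                measured = X["ldl_mgdl"].to_numpy(float)
                ldl_fw = np.where(np.isfinite(measured), measured, ldl_fw)
            out["ldl_derived"] = ldl_fw
            out["vldl_derived"] = vldl
        return out


def _guard(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """NaN out entries whose inputs violate the operation's domain."""
    return np.where(valid, values, np.nan)


def compute_panel(cohort: pd.DataFrame, **params) -> pd.DataFrame:
    """Derive the index panel for a cohort frame (functional wrapper)."""
    return InsulinResistanceIndices(**params).fit(cohort).transform(cohort)
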