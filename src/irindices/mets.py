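"""NCEP ATP III metabolic-syndrome classification (Asian waist thresholds).

A subject is classified MetS-positive when at least three of five criteria
hold: central obesity (waist ≥ 90 cm men / 80 cm women), raised blood
pressure (SBP ≥ 130 or DBP ≥ 85 mmHg), raised triglycerides (≥ 150 mg/dL),
reduced HDL-C (< 40 mg/dL men / < 50 mg/dL women), and raised fasting
glucose (≥ 100 mg/dL).  The inclusive/exclusive reading of the boundary
("over 90 cm" vs the canonical ≥ 90) is switchable; HDL stays strictly
``<`` under both conventions.

Also provides the Asian-specific BMI categorisation (underweight < 18.5,
normal 18.5-22.9, overweight 23-24.9, obese ≥ 25 kg/m²) and the 0.9 / 0.8
waist-hip-ratio flags.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

CRITERIA = ("waist", "bp", "tg", "hdl", "fpg")

BMI_LABELS = ("underweight", "normal", "overweight", "obese")
#: Left-closed bin edges of the Southeast-Asian BMI categories (kg/m²).
BMI_EDGES = (18.5, 23.0, 25.0)

WHR_CUTOFF = {"M": 0.9, "F": 0.8}


@dataclass(frozen=True)
class ATPIIIThresholds:
    """Criterion thresholds of the NCEP ATP III rule (Asian waist values)."""

    waist_male: float = 90.0    # cm
    waist_female: float = 80.0  # cm
    sbp: float = 130.0          # mmHg
    dbp: float = 85.0           # mmHg
    tg: float = 150.0           # mg/dL
    hdl_male: float = 40.0      # mg/dL
    hdl_female: float = 50.0    # mg/dL
    fpg: float = 100.0          # mg/dL
    min_criteria: int = 3

    def __post_init__(self) -> None:
        if not all(v > 0 for k, v in asdict(self).items() if k != "min_criteria"):
            raise ValueError("all thresholds must be positive")
        if not 1 <= self.min_criteria <= 5:
            raise ValueError("min_criteria must be in 1..5")


class ATPIIIClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based MetS classifier over a cohort DataFrame.

    ``predict`` returns 0/1 MetS status; ``criteria`` returns the five
    boolean criterion flags plus the criterion count.  The rule has no
    free parameters to estimate, so ``fit`` only records the class labels
    for scikit-learn compatibility.

    Parameters
    ----------
    thresholds : ATPIIIThresholds
        Criterion thresholds; defaults are the Asian-modified ATP III set.
    convention : {"gte", "strict"}, default "gte"
        Boundary handling for the four "raised" criteria: ``gte`` flags
        values equal to the threshold (canonical ATP III), ``strict``
        requires strict exceedance.  HDL is strictly ``<`` either way.
    """

    def __init__(
        self,
        thresholds: ATPIIIThresholds | None = None,
        convention: str = "gte",
    ):
        self.thresholds = thresholds
        self.convention = convention

    def _thresholds(self) -> ATPIIIThresholds:
        return self.thresholds if self.thresholds is not None else ATPIIIThresholds()

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "ATPIIIClassifier":
        if self.convention not in ("gte", "strict"):
            raise ValueError(f"convention must be 'gte' or 'strict', got {self.convention!r}")
        self.classes_ = np.array([0, 1])
        return self

    def criteria(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-subject criterion flags, criterion count and MetS status.

        Rows with any required field missing get NaN flags and a missing
        status (classification refused, never silently negative).
        """
        self.fit()
        t = self._thresholds()
        ge = np.greater_equal if self.convention == "gte" else np.greater

        required = ["sex", "waist_cm", "sbp_mmhg", "dbp_mmhg", "tg_mgdl", "hdl_mgdl", "fpg_mgdl"]
        missing_cols = [c for c in required if c not in X.columns]
        if missing_cols:
            raise ValueError(f"cohort frame missing column(s): {', '.join(missing_cols)}")

        sex = X["sex"].to_numpy()
        male = sex == "M"
        waist = X["waist_cm"].to_numpy(float)
        sbp = X["sbp_mmhg"].to_numpy(float)
        dbp = X["dbp_mmhg"].to_numpy(float)
        tg = X["tg_mgdl"].to_numpy(float)
        hdl = X["hdl_mgdl"].to_numpy(float)
        fpg = X["fpg_mgdl"].to_numpy(float)

        complete = (
            np.isin(sex, ("M", "F"))
            & np.isfinite(waist) & np.isfinite(sbp) & np.isfinite(dbp)
            & np.isfinite(tg) & np.isfinite(hdl) & np.isfinite(fpg)
        )

        with np.errstate(invalid="ignore"):
            flags = pd.DataFrame(index=X.index)
            flags["waist"] = ge(waist, np.where(male, t.waist_male, t.waist_female))
            flags["bp"] = ge(sbp, t.sbp) | ge(dbp, t.dbp)
            flags["tg"] = ge(tg, t.tg)
            flags["hdl"] = hdl < np.where(male, t.hdl_male, t.hdl_female)
            flags["fpg"] = ge(fpg, t.fpg)

        flags = flags.astype(float).where(pd.Series(complete, index=X.index), np.nan)
        n = flags.sum(axis=1, skipna=False)
        out = flags.copy()
        out["n_criteria"] = n
        out["mets"] = (n >= t.min_criteria).astype(float).where(n.notna(), np.nan)
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """0/1 MetS status; raises if any subject cannot be classified."""
        mets = self.criteria(X)["mets"]
        if mets.isna().any():
            bad = list(X.loc[mets.isna()].get("id", mets.index[mets.isna()]))
            raise ValueError(f"classification refused for subject(s) with missing fields: {bad}")
        return mets.to_numpy(int)


def classify_mets(
    X: pd.DataFrame,
    thresholds: ATPIIIThresholds | None = None,
    convention: str = "gte",
) -> pd.DataFrame:
    """Functional wrapper: criterion flags + count + status for a cohort."""
    return ATPIIIClassifier(thresholds=thresholds, convention=convention).fit().criteria(X)


def bmi_category(bmi: float | np.ndarray) -> np.ndarray | str:
    """Southeast-Asian BMI category; intervals are closed on the left."""
    arr = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("BMI must be finite")
    idx = np.searchsorted(BMI_EDGES, arr, side="right")
    labels = np.array(BMI_LABELS, dtype=object)
    return str(labels[int(idx)]) if arr.ndim == 0 else labels[idx]


def whr_flag(sex: str, whr: float) -> bool:
    """Central-obesity flag at WHR ≥ 0.9 (men) / 0.8 (women)."""
    if sex not in WHR_CUTOFF:
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    if whr <= 0:
        raise ValueError(f"whr must be positive, got {whr}")
    return whr >= WHR_CUTOFF[sex]
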