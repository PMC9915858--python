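"""Cohort table schema, subject records, and CSV I/O.

The on-disk format is a plain UTF-8, comma-separated table with one row per
subject and the exact header below.  Units are encoded in the column names
(cm, kg, mmHg, mg/dL, uIU/mL); ``sex`` is ``M`` or ``F``; empty cells are
missing values.  ``ldl_mgdl`` is optional — when absent it is derived from
the lipid panel by the Friedewald formula downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns, in canonical order.
COHORT_COLUMNS: tuple[str, ...] = (
    "id",
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    "waist_cm",
    "hip_cm",
    "sbp_mmhg",
    "dbp_mmhg",
    "fpg_mgdl",
    "insulin_uiu_ml",
    "tc_mgdl",
    "hdl_mgdl",
    "tg_mgdl",
)

#: Columns that may be absent from the file entirely.
OPTIONAL_COLUMNS: tuple[str, ...] = ("ldl_mgdl",)

NUMERIC_COLUMNS: tuple[str, ...] = tuple(
    c for c in COHORT_COLUMNS if c not in ("id", "sex")
) + OPTIONAL_COLUMNS

#: Columns that must be strictly positive when present.
_POSITIVE = ("height_cm", "weight_kg", "waist_cm", "hip_cm")


class SchemaError(ValueError):
    """Raised when a cohort file does not conform to the schema."""


@dataclass
class SubjectRecord:
    """One participant's raw anthropometry, blood pressure and fasting labs.

    All lab values are in the conventional US units the assays report
    (mg/dL; insulin in μIU/mL); anthropometry in cm/kg; pressures in mmHg.
    Missing optional values are ``nan``.
    """

    id: str
    sex: str  # "M" or "F"
    age: float
    height_cm: float
    weight_kg: float
    waist_cm: float
    hip_cm: float
    sbp_mmhg: float
    dbp_mmhg: float
    fpg_mgdl: float
    insulin_uiu_ml: float
    tc_mgdl: float
    hdl_mgdl: float
    tg_mgdl: float
    ldl_mgdl: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in _POSITIVE:
            v = getattr(self, name)
            if np.isfinite(v) and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for f in dc_fields(self):
            if f.name in ("id", "sex"):
                continue
            v = getattr(self, f.name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Stack records into a cohort DataFrame in canonical column order."""
    rows = [vars(r) for r in records]
    df = pd.DataFrame(rows)
    return df[list(COHORT_COLUMNS) + [c for c in OPTIONAL_COLUMNS if c in df]]


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    """Inverse of :func:`records_to_frame`."""
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        recs.append(SubjectRecord(**{k: d[k] for k in d if k in _FIELD_NAMES}))
    return recs


_FIELD_NAMES = {f.name for f in dc_fields(SubjectRecord)}


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the schema, dropping bad rows.

    Hard errors (missing required column, unknown sex level in every row)
    raise :class:`SchemaError`; row-level problems (unparsable numbers,
    non-positive anthropometry) drop the row with a logged warning carrying
    the row position.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    extra = [
        c for c in df.columns if c not in COHORT_COLUMNS + OPTIONAL_COLUMNS
    ]
    if extra:
        raise SchemaError(f"unknown column(s): {', '.join(extra)}")

    out = df.copy()
    out["id"] = out["id"].astype(str)
    out["sex"] = out["sex"].astype(str).str.strip().str.upper()
    for c in NUMERIC_COLUMNS:
        if c in out.columns:
            out[c] = pd.to_numeric(out[c], errors="coerce")
    for c in OPTIONAL_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan

    bad_sex = ~out["sex"].isin(["M", "F"])
    # required numerics: anthropometry must parse and be positive
    bad_pos = pd.Series(False, index=out.index)
    for c in _POSITIVE:
        bad_pos |= ~(out[c] > 0)
    bad_neg = pd.Series(False, index=out.index)
    for c in NUMERIC_COLUMNS:
        if c not in _POSITIVE:
            bad_neg |= out[c] < 0
    bad = bad_sex | bad_pos | bad_neg
    if bad.any():
        for pos in np.flatnonzero(bad.to_numpy()):
            logger.warning(
                "dropping cohort row %d (id=%s): failed validation",
                pos + 1,
                out.iloc[pos]["id"],
            )
        out = out.loc[~bad]
    if out.empty:
        raise SchemaError("no valid rows in cohort table")
    return out.reset_index(drop=True)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Returns the validated DataFrame; use :func:`frame_to_records` for typed
    per-subject records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table in the canonical column order."""
    cols = [c for c in COHORT_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols, float_format="%.10g")
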