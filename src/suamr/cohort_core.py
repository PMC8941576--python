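"""Core cohort domain: participant records, unit handling, the exclusion
cascade and the liver scoring / classification rules.

All internal uric-acid values are in mg/dl; μmol/l appears only at I/O
boundaries through :func:`convert_sua` (conversion constant 59.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError

__all__ = [
    "ParticipantRecord",
    "ExclusionReport",
    "apply_exclusions",
    "compute_apri",
    "compute_fib4",
    "classify_elevated",
    "convert_sua",
    "bmi_category",
    "UMOL_PER_MG_DL",
    "DEFAULT_AST_ULN",
    "DEFAULT_BMI_CUTOFF",
    "ALCOHOL_LIMIT_GPW",
    "ELEVATED_CUTOFFS",
]

#: μmol/l per mg/dl of uric acid (study convention, not the physical 59.48).
UMOL_PER_MG_DL = 59.5

#: Conventional laboratory upper limit of normal for AST (U/l); configurable.
DEFAULT_AST_ULN = 40.0

#: Chinese adult overweight cutoff (kg/m²); configurable.
DEFAULT_BMI_CUTOFF = 24.0

#: Excessive weekly alcohol intake, grams/week, by sex; exceeding is exclusion.
ALCOHOL_LIMIT_GPW = {"male": 210.0, "female": 140.0}

#: Strict ">" cutoffs for elevated-marker classification, per marker and sex.
ELEVATED_CUTOFFS = {
    "ALT": {"male": 30.0, "female": 19.0},
    "GGT": {"male": 51.0, "female": 33.0},
    "APRI": {"male": 0.5, "female": 0.5},
    "FIB4": {"male": 2.67, "female": 2.67},
}


@dataclass
class ParticipantRecord:
    """One subject's demographics, lifestyle, labs and fatty-liver status.

    Numeric labs may be ``None`` when missing; NAFLD flags are only
    meaningful when the corresponding ultrasound flag is true.
    """

    id: str
    sex: str  # "male" | "female"
    age: float
    bmi: float
    waist: Optional[float] = None
    smoking: str = "never"  # never | quit | current
    drinking: str = "never"
    physical_activity: bool = True
    history_diabetes: bool = False
    history_chd: bool = False
    history_hypertension: bool = False
    glucose_lowering_med: bool = False
    sua_lowering_med: bool = False
    nafld_assoc_med: bool = False
    chronic_hepatitis: bool = False
    cirrhosis: bool = False
    hbsag_positive: bool = False
    alcohol_gpw: float = 0.0
    sua: Optional[float] = None  # mg/dl
    alt: Optional[float] = None  # U/l
    ast: Optional[float] = None  # U/l
    ggt: Optional[float] = None  # U/l
    plt: Optional[float] = None  # 10^9/l
    fpg: Optional[float] = None  # mmol/l
    cre: Optional[float] = None  # μmol/l
    tg: Optional[float] = None
    tc: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    ultrasound_done_baseline: bool = True
    ultrasound_done_followup: bool = True
    nafld_baseline: Optional[bool] = False
    nafld_followup: Optional[bool] = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise InvalidParameterError(f"sex must be male/female, got {self.sex!r}")
        if self.age is not None and not self.age > 0:
            raise InvalidParameterError("age must be positive")
        if self.bmi is not None and not self.bmi > 0:
            raise InvalidParameterError("bmi must be positive")
        for name in ("sua", "plt"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v <= 0:
                raise InvalidParameterError(f"{name} must be positive when present")


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Convert ParticipantRecord objects to the canonical cohort table."""
    rows = [{f.name: getattr(r, f.name) for f in fields(ParticipantRecord)} for r in records]
    if not rows:
        raise EmptyInputError("no participant records")
    return pd.DataFrame(rows).rename(columns={"id": "participant_id"})


@dataclass
class ExclusionReport:
    """Ordered accounting of how many records each criterion removed.

    Each record is attributed to the first criterion that matches it, so
    the removal counts are order-dependent and sum to initial − retained.
    """

    initial: int
    steps: list[tuple[str, int]] = field(default_factory=list)
    retained: int = 0

    @property
    def total_removed(self) -> int:
        return sum(n for _, n in self.steps)

    def check(self) -> None:
        if self.initial - self.total_removed != self.retained:
            raise AssertionError("exclusion counts do not conserve records")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["criterion", "removed"])


def _flag(df: pd.DataFrame, col: str) -> pd.Series:
    if col not in df.columns:
        return pd.Series(False, index=df.index)
    return df[col].fillna(False).astype(bool)


# (name, mask function); masks are evaluated sequentially on the surviving
# rows, so each removal is attributed to the first matching criterion.
_EXCLUSION_CRITERIA = [
    ("chronic_hepatitis", lambda d: _flag(d, "chronic_hepatitis")),
    ("cirrhosis", lambda d: _flag(d, "cirrhosis")),
    (
        "excessive_alcohol",
        lambda d: (
            ((d["sex"] == "male") & (d["alcohol_gpw"] > ALCOHOL_LIMIT_GPW["male"]))
            | ((d["sex"] == "female") & (d["alcohol_gpw"] > ALCOHOL_LIMIT_GPW["female"]))
        ).fillna(False),
    ),
    ("nafld_associated_medication", lambda d: _flag(d, "nafld_assoc_med")),
    ("missing_baseline_ultrasound", lambda d: ~_flag(d, "ultrasound_done_baseline")),
    ("nafld_at_baseline", lambda d: _flag(d, "nafld_baseline")),
    ("hbsag_positive", lambda d: _flag(d, "hbsag_positive")),
    ("cirrhosis_followup", lambda d: _flag(d, "cirrhosis")),
    ("nafld_associated_medication_followup", lambda d: _flag(d, "nafld_assoc_med")),
    ("missing_followup_ultrasound", lambda d: ~_flag(d, "ultrasound_done_followup")),
    (
        "missing_sua_age_bmi",
        lambda d: d["sua"].isna() | d["age"].isna() | d["bmi"].isna(),
    ),
    ("sua_lowering_medication", lambda d: _flag(d, "sua_lowering_med")),
]


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the two-stage participant exclusion cascade in narrative order.

    Baseline stage: chronic hepatitis, cirrhosis, excessive alcohol
    (> 210 g/week men, > 140 g/week women — strict), NAFLD-associated
    medication, missing baseline ultrasound, fatty liver already present at
    baseline.  Follow-up stage: HBsAg positivity, cirrhosis, medication
    (again, catching new data), missing follow-up ultrasound, missing
    SUA/age/BMI, uric-acid-lowering medication.

    Returns the retained table and an :class:`ExclusionReport`.
    """
    if table is None or len(table) == 0:
        raise EmptyInputError("exclusion cascade requires a nonempty table")
    report = ExclusionReport(initial=len(table))
    current = table
    for name, mask_fn in _EXCLUSION_CRITERIA:
        mask = mask_fn(current)
        removed = int(mask.sum())
        report.steps.append((name, removed))
        if removed:
            current = current.loc[~mask]
    report.retained = len(current)
    report.check()
    return current.copy(), report


def compute_apri(ast, ast_uln: float = DEFAULT_AST_ULN, plt=None):
    """AST-to-platelet ratio index: (AST / ULN) / PLT × 100.

    Accepts scalars or arrays; PLT in 10⁹/l.
    """
    if plt is None:
        raise InvalidParameterError("plt is required")
    ast = np.asarray(ast, dtype=float)
    plt_arr = np.asarray(plt, dtype=float)
    if not ast_uln > 0:
        raise InvalidParameterError("ast_uln must be positive")
    if np.any(plt_arr <= 0):
        raise InvalidParameterError("plt must be positive")
    out = (ast / ast_uln) / plt_arr * 100.0
    return float(out) if out.ndim == 0 else out


def compute_fib4(age, ast, alt, plt):
    """FIB-4 index: age × AST / (PLT × √ALT)."""
    age = np.asarray(age, dtype=float)
    ast = np.asarray(ast, dtype=float)
    alt = np.asarray(alt, dtype=float)
    plt_arr = np.asarray(plt, dtype=float)
    if np.any(alt <= 0):
        raise InvalidParameterError("alt must be positive")
    if np.any(plt_arr <= 0):
        raise InvalidParameterError("plt must be positive")
    out = age * ast / (plt_arr * np.sqrt(alt))
    return float(out) if out.ndim == 0 else out


def classify_elevated(marker: str, value, sex):
    """Strict ">" classification against the per-sex elevated-marker cutoffs.

    Cutoffs: ALT 30/19 (M/F), GGT 51/33 (M/F), APRI 0.5, FIB4 2.67.
    Accepts scalar or array ``value``/``sex``.
    """
    try:
        cutoffs = ELEVATED_CUTOFFS[marker]
    except KeyError:
        raise InvalidParameterError(f"unknown marker {marker!r}") from None
    value = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(value)):
        raise InvalidParameterError("marker value must be finite")
    sex_arr = np.asarray(sex)
    cut = np.where(sex_arr == "female", cutoffs["female"], cutoffs["male"])
    out = value > cut
    return bool(out) if out.ndim == 0 else out


def convert_sua(value, unit: str):
    """Convert uric acid to mg/dl; μmol/l is divided by 59.5."""
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise InvalidParameterError("uric acid cannot be negative")
    if unit == "mg_per_dl":
        out = value
    elif unit == "umol_per_l":
        out = value / UMOL_PER_MG_DL
    else:
        raise InvalidParameterError(f"unknown unit {unit!r}")
    return float(out) if out.ndim == 0 else out


def bmi_category(bmi, cutoff: float = DEFAULT_BMI_CUTOFF):
    """Dichotomize BMI: 'normal' below ``cutoff``, else 'overweight_obese'."""
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi <= 0):
        raise InvalidParameterError("bmi must be positive")
    out = np.where(bmi < cutoff, "normal", "overweight_obese")
    return str(out[()]) if out.ndim == 0 else out


def derive_diabetes(df: pd.DataFrame) -> pd.Series:
    """Diabetes = glucose-lowering medication, FPG ≥ 7.0 mmol/l, or history."""
    fpg_high = df["fpg"].ge(7.0).fillna(False) if "fpg" in df else False
    return (_flag(df, "glucose_lowering_med") | fpg_high | _flag(df, "history_diabetes"))


def add_derived_columns(
    df: pd.DataFrame,
    ast_uln: float = DEFAULT_AST_ULN,
    bmi_cutoff: float = DEFAULT_BMI_CUTOFF,
) -> pd.DataFrame:
    """Attach apri, fib4, diabetes, bmi_category and elevated-marker flags."""
    out = df.copy()
    out["apri"] = compute_apri(out["ast"], ast_uln, plt=out["plt"])
    out["fib4"] = compute_fib4(out["age"], out["ast"], out["alt"], out["plt"])
    out["diabetes"] = derive_diabetes(out).astype(int)
    out["bmi_category"] = bmi_category(out["bmi"], cutoff=bmi_cutoff)
    marker_col = {"ALT": "alt", "GGT": "ggt", "APRI": "apri", "FIB4": "fib4"}
    for marker, col in marker_col.items():
        out[f"elevated_{col}"] = classify_elevated(
            marker, out[col].to_numpy(), out["sex"].to_numpy()
        ).astype(int)
    return out
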