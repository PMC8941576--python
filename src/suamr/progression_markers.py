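"""Hepatic necroinflammation and estimated-fibrosis analyses among
incident-NAFLD participants: covariance-adjusted mean differences across
exposure quartiles and logistic odds of elevated markers, with per-mg/dl
odds ratios in sex and BMI subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._modeling import Z95, build_design, complete_cases, fit_logistic, fit_ols
from .errors import InvalidParameterError
from .observational_association import (
    AdjustmentSet,
    Covariate,
    EffectEstimate,
    QuartileScheme,
    fit_per_unit_or,
    fit_quartile_or,
    stratified_analysis,
)

__all__ = [
    "AdjustedMeanDifference",
    "MARKER_COLUMNS",
    "progression_adjustment",
    "adjusted_mean_differences",
    "elevated_marker_or",
]

MARKER_COLUMNS = {"ALT": "alt", "GGT": "ggt", "APRI": "apri", "FIB4": "fib4"}

_BASE_COVARIATES = (
    Covariate("sex", "categorical", reference="male"),
    Covariate("bmi"),
    Covariate("smoking", "categorical", reference="never"),
    Covariate("drinking", "categorical", reference="never"),
    Covariate("physical_activity"),
    Covariate("cre"),
    Covariate("fpg"),
    Covariate("history_hypertension"),
    Covariate("history_chd"),
    Covariate("diabetes"),
)


def progression_adjustment(marker: str, with_age: bool = True) -> AdjustmentSet:
    """Adjustment set for the progression models.

    Age is never adjusted for when the marker is FIB4 (age sits inside the
    score's formula); for the other markers it is included iff ``with_age``.
    The mean-difference models omit age by default; the elevated-marker
    models include it.
    """
    covs = _BASE_COVARIATES
    if with_age and marker != "FIB4":
        covs = (Covariate("age"),) + covs
    return AdjustmentSet(name=f"progression_{marker.lower()}", covariates=covs)


@dataclass(frozen=True)
class AdjustedMeanDifference:
    """Covariance-adjusted marker difference versus Q1, in marker units.

    Q1 itself is represented with a difference of exactly 0 and a degenerate
    CI."""

    marker: str
    quartile: int
    difference: float
    ci_low: float
    ci_high: float
    n: int


def adjusted_mean_differences(
    nafld_table: pd.DataFrame,
    marker: str,
    scheme: QuartileScheme,
    adjustment: AdjustmentSet,
    exposure: str = "sua",
) -> list[AdjustedMeanDifference]:
    """Linear model of the marker on quartile indicators plus covariates;
    Q2–Q4 coefficients are the adjusted mean differences versus Q1."""
    col = MARKER_COLUMNS.get(marker)
    if col is None:
        raise InvalidParameterError(f"unknown marker {marker!r}")
    df = complete_cases(nafld_table, [col, exposure, "sex", *adjustment.names])
    q = scheme.assign_frame(df, exposure)
    df = df.loc[q > 0]
    q = q.loc[df.index]
    X = pd.DataFrame({f"Q{k}": (q == k).astype(float) for k in (2, 3, 4)}, index=df.index)
    X = pd.concat([X, build_design(df, adjustment.covariates)], axis=1)
    res = fit_ols(df[col], X, f"mean_diff[{marker}]")
    n = int(len(df))
    out = [AdjustedMeanDifference(marker, 1, 0.0, 0.0, 0.0, n)]
    for k in (2, 3, 4):
        b = float(res.params[f"Q{k}"])
        se = float(res.bse[f"Q{k}"])
        out.append(
            AdjustedMeanDifference(marker, k, b, b - Z95 * se, b + Z95 * se, n)
        )
    return out


@dataclass
class ElevatedMarkerResult:
    """Quartile ORs of the elevated-marker outcome, its per-mg/dl OR, and
    per-mg/dl ORs in sex and BMI subgroups; carries the covariate names
    actually used so the FIB4 no-age rule is inspectable."""

    marker: str
    quartile_estimates: dict  # 2,3,4 -> EffectEstimate
    trend_p: float
    percent_elevated: dict  # 1..4 -> percent
    per_unit: EffectEstimate
    subgroups: dict  # ("sex", level) / ("bmi_category", level) -> EffectEstimate
    covariate_names: tuple[str, ...]


def elevated_marker_or(
    nafld_table: pd.DataFrame,
    marker: str,
    scheme: QuartileScheme,
    adjustment: AdjustmentSet | None = None,
    exposure: str = "sua",
) -> ElevatedMarkerResult:
    """Logistic models of the elevated-marker flag on exposure quartiles and
    on the continuous exposure, overall and within sex/BMI subgroups.

    The elevated flag must already be present (``elevated_<marker>``, from
    the strict-cutoff classifier).  When marker is FIB4 the adjustment set
    provably excludes age.
    """
    col = MARKER_COLUMNS.get(marker)
    if col is None:
        raise InvalidParameterError(f"unknown marker {marker!r}")
    outcome = f"elevated_{col}"
    if outcome not in nafld_table.columns:
        raise InvalidParameterError(f"column {outcome!r} missing; derive it first")
    if adjustment is None:
        adjustment = progression_adjustment(marker, with_age=True)
    elif marker == "FIB4" and "age" in adjustment.names:
        adjustment = adjustment.drop("age")

    qres = fit_quartile_or(nafld_table, outcome, scheme, adjustment, exposure=exposure)

    df = complete_cases(nafld_table, [outcome, exposure, "sex"])
    q = scheme.assign_frame(df, exposure)
    pct = {
        k: float(100.0 * df.loc[q == k, outcome].mean()) for k in (1, 2, 3, 4)
    }

    per_unit = fit_per_unit_or(nafld_table, outcome, adjustment, exposure=exposure)
    subgroups = {}
    for strata in ("sex", "bmi_category"):
        if strata not in nafld_table.columns:
            continue
        res = stratified_analysis(
            nafld_table, strata, fit_per_unit_or, adjustment, outcome=outcome, exposure=exposure
        )
        for level, est in res.items():
            subgroups[(strata, level)] = est

    return ElevatedMarkerResult(
        marker=marker,
        quartile_estimates=qres.estimates,
        trend_p=qres.trend_p,
        percent_elevated=pct,
        per_unit=per_unit,
        subgroups=subgroups,
        covariate_names=adjustment.names,
    )
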