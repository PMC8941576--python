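"""Sex-specific uric-acid quartiles and the logistic association models:
crude, age/sex-adjusted, multivariable models 1 and 2, trend tests,
per-unit odds ratios and sex/BMI-stratified analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from ._modeling import Z95, build_design, complete_cases, fit_logistic
from .cohort_core import UMOL_PER_MG_DL
from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "Covariate",
    "AdjustmentSet",
    "QuartileScheme",
    "EffectEstimate",
    "QuartileORResult",
    "adjustment_set",
    "compute_quartile_scheme",
    "fit_quartile_or",
    "fit_per_unit_or",
    "stratified_analysis",
]


@dataclass(frozen=True)
class Covariate:
    name: str
    kind: str = "continuous"  # continuous | categorical
    reference: Optional[object] = None


@dataclass(frozen=True)
class AdjustmentSet:
    """Named, ordered covariate list used to adjust a regression model."""

    name: str
    covariates: tuple[Covariate, ...] = ()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def drop(self, *names: str) -> "AdjustmentSet":
        """Return a copy without the given covariates (used when a variable
        becomes a stratification axis or sits inside the outcome formula)."""
        kept = tuple(c for c in self.covariates if c.name not in names)
        return replace(self, name=f"{self.name}_minus_{'_'.join(names)}", covariates=kept)

    def plus(self, *covs: Covariate) -> "AdjustmentSet":
        return replace(self, covariates=self.covariates + covs)


_LIFESTYLE = (
    Covariate("smoking", "categorical", reference="never"),
    Covariate("drinking", "categorical", reference="never"),
    Covariate("physical_activity", "continuous"),
)
_COMORBID_LABS = (
    Covariate("history_chd", "continuous"),
    Covariate("history_hypertension", "continuous"),
    Covariate("diabetes", "continuous"),
    Covariate("alt", "continuous"),
    Covariate("cre", "continuous"),
    Covariate("fpg", "continuous"),
)

_ADJUSTMENTS = {
    "univariate": AdjustmentSet("univariate"),
    "age_sex": AdjustmentSet(
        "age_sex",
        (Covariate("age"), Covariate("sex", "categorical", reference="male")),
    ),
    "model1": AdjustmentSet(
        "model1",
        (
            Covariate("age"),
            Covariate("sex", "categorical", reference="male"),
            Covariate("bmi"),
        )
        + _LIFESTYLE,
    ),
    "model2": AdjustmentSet(
        "model2",
        (
            Covariate("age"),
            Covariate("sex", "categorical", reference="male"),
            Covariate("bmi"),
        )
        + _LIFESTYLE
        + _COMORBID_LABS,
    ),
}


def adjustment_set(name: str) -> AdjustmentSet:
    """Look up one of the predefined adjustment sets
    (univariate, age_sex, model1, model2)."""
    try:
        return _ADJUSTMENTS[name]
    except KeyError:
        raise InvalidParameterError(f"unknown adjustment set {name!r}") from None


@dataclass(frozen=True)
class QuartileScheme:
    """Per-sex cutoff triples with left-closed assignment:
    Q1 = x < c1; Qk = c(k−1) ≤ x < ck; Q4 = x ≥ c3."""

    cutoffs: dict  # sex -> (c1, c2, c3)

    def __post_init__(self):
        for sex, cuts in self.cutoffs.items():
            if not (cuts[0] < cuts[1] < cuts[2]):
                raise InvalidParameterError(
                    f"cutoffs must be strictly increasing for {sex}: {cuts}"
                )

    def assign(self, values, sex) -> np.ndarray:
        """Quartile index 1..4 for each value, using its sex's cutoffs;
        NaN values map to 0 (unassigned)."""
        values = np.asarray(values, dtype=float)
        sex = np.asarray(sex)
        out = np.zeros(values.shape, dtype=int)
        for s, cuts in self.cutoffs.items():
            m = sex == s
            out[m] = np.digitize(values[m], cuts, right=False) + 1
        out[np.isnan(values)] = 0
        return out

    def assign_frame(self, df: pd.DataFrame, variable: str = "sua") -> pd.Series:
        return pd.Series(
            self.assign(df[variable].to_numpy(), df["sex"].to_numpy()),
            index=df.index,
            name="sua_quartile",
        )


@dataclass(frozen=True)
class EffectEstimate:
    """A coefficient on a stated scale with its Wald CI.

    ``beta`` is the log-odds (or linear) coefficient; ``ci_low``/``ci_high``
    are on the reported (odds-ratio) scale for logistic estimates.
    """

    scale: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def _logit_estimate(res, term: str, n: int, scale: str) -> EffectEstimate:
    beta = float(res.params[term])
    se = float(res.bse[term])
    return EffectEstimate(
        scale=scale,
        beta=beta,
        se=se,
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p=float(res.pvalues[term]),
        n=n,
    )


def compute_quartile_scheme(
    table: pd.DataFrame, variable: str = "sua", sex_col: str = "sex"
) -> QuartileScheme:
    """Within-sex 25/50/75th percentiles (linear-interpolation rule) of the
    variable among analyzed records."""
    cutoffs = {}
    for sex, grp in table.groupby(sex_col, observed=True):
        vals = grp[variable].dropna().to_numpy(dtype=float)
        if len(vals) < 4:
            raise InsufficientDataError(
                f"need ≥4 non-missing {variable} values for sex={sex}, got {len(vals)}"
            )
        c = np.percentile(vals, [25, 50, 75])
        if not (c[0] < c[1] < c[2]):
            raise InsufficientDataError(
                f"degenerate {variable} distribution for sex={sex}: cutoffs {tuple(c)}"
            )
        cutoffs[sex] = (float(c[0]), float(c[1]), float(c[2]))
    return QuartileScheme(cutoffs)


@dataclass
class QuartileORResult:
    """Q2–Q4 odds ratios versus Q1 plus the ordinal trend test."""

    estimates: dict  # quartile (2,3,4) -> EffectEstimate
    trend_p: float
    n: int
    adjustment: str
    covariate_names: tuple[str, ...] = field(default_factory=tuple)


def _prepare(table, outcome, adjustment, extra_cols):
    cols = [outcome, *extra_cols, *adjustment.names]
    return complete_cases(table, cols)


def fit_quartile_or(
    table: pd.DataFrame,
    outcome: str,
    scheme: QuartileScheme,
    adjustment: AdjustmentSet,
    exposure: str = "sua",
    trend: str = "index",
) -> QuartileORResult:
    """Logistic model of the outcome on Q2/Q3/Q4 indicators (Q1 reference)
    plus the adjustment covariates; Wald CIs.

    The trend P comes from a separate fit replacing the indicators with the
    ordinal quartile index entered as continuous (``trend="index"``) or with
    within-quartile exposure medians (``trend="median"``).
    """
    df = _prepare(table, outcome, adjustment, [exposure, "sex"])
    q = scheme.assign_frame(df, exposure)
    df = df.loc[q > 0]
    q = q.loc[df.index]

    X = pd.DataFrame(
        {f"Q{k}": (q == k).astype(float) for k in (2, 3, 4)}, index=df.index
    )
    Xadj = build_design(df, adjustment.covariates)
    Xfull = pd.concat([X, Xadj], axis=1)
    y = df[outcome].astype(float)
    res = fit_logistic(y, Xfull, f"quartile_or[{adjustment.name}]", focus=["Q2", "Q3", "Q4"])
    n = int(len(df))
    estimates = {
        k: _logit_estimate(res, f"Q{k}", n, scale=f"quartile_{k}_vs_1") for k in (2, 3, 4)
    }

    if trend == "index":
        trend_var = q.astype(float)
    elif trend == "median":
        med = df[exposure].groupby(q).median()
        trend_var = q.map(med).astype(float)
    else:
        raise InvalidParameterError(f"unknown trend rule {trend!r}")
    Xt = pd.concat([trend_var.rename("trend"), Xadj], axis=1)
    res_t = fit_logistic(y, Xt, f"trend[{adjustment.name}]", focus="trend")
    return QuartileORResult(
        estimates=estimates,
        trend_p=float(res_t.pvalues["trend"]),
        n=n,
        adjustment=adjustment.name,
        covariate_names=adjustment.names,
    )


def fit_per_unit_or(
    table: pd.DataFrame,
    outcome: str,
    adjustment: AdjustmentSet,
    unit: str = "mg_per_dl",
    exposure: str = "sua",
) -> EffectEstimate:
    """Logistic odds ratio per unit of the continuous exposure.

    The model is fitted once on the mg/dl scale; the μmol/l estimate is an
    exact rescaling of the same coefficient, so
    OR_mgdl = OR_umol ** 59.5 holds identically.
    """
    if unit not in ("mg_per_dl", "umol_per_l"):
        raise InvalidParameterError(f"unknown unit {unit!r}")
    df = _prepare(table, outcome, adjustment, [exposure])
    Xadj = build_design(df, adjustment.covariates)
    X = pd.concat([df[exposure].astype(float), Xadj], axis=1)
    res = fit_logistic(df[outcome].astype(float), X, f"per_unit_or[{adjustment.name}]", focus=exposure)
    n = int(len(df))
    est = _logit_estimate(res, exposure, n, scale="per_mg_dl")
    if unit == "umol_per_l":
        beta = est.beta / UMOL_PER_MG_DL
        se = est.se / UMOL_PER_MG_DL
        est = EffectEstimate(
            scale="per_umol_l",
            beta=beta,
            se=se,
            ci_low=float(np.exp(beta - Z95 * se)),
            ci_high=float(np.exp(beta + Z95 * se)),
            p=est.p,
            n=n,
        )
    return est


_STRATUM_TO_COVARIATE = {"sex": ("sex",), "bmi_category": ("bmi", "bmi_category")}


def stratified_analysis(
    table: pd.DataFrame,
    strata: str,
    analysis: Callable,
    adjustment: AdjustmentSet,
    **kwargs,
) -> dict:
    """Run ``analysis(stratum_table, adjustment=..., **kwargs)`` per level of
    the stratification variable, dropping that variable (and its source
    column, e.g. bmi for bmi_category) from the adjustment set."""
    if strata not in table.columns:
        raise InvalidParameterError(f"stratification column {strata!r} missing")
    dropped = _STRATUM_TO_COVARIATE.get(strata, (strata,))
    adj = adjustment.drop(*dropped)
    out = {}
    for level, grp in table.groupby(strata, observed=True):
        if len(grp) == 0:
            raise InsufficientDataError(f"empty stratum {strata}={level}")
        out[level] = analysis(grp, adjustment=adj, **kwargs)
    if not out:
        raise InsufficientDataError(f"no strata found for {strata}")
    return out
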