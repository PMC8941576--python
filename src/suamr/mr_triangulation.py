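"""One-sample Mendelian-randomization triangulation: compose the expected
genetic effect on the outcome from the instrument-exposure and
exposure-outcome effects, estimate the observed genetic effect, and compare
the two with the Altman–Bland interaction test.  Includes an approximate
power calculation for per-allele effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._modeling import Z95, build_design, complete_cases, fit_logistic
from .errors import InvalidParameterError, ScaleMismatchError
from .genetic_instruments import InstrumentSummary
from .observational_association import AdjustmentSet, EffectEstimate

__all__ = [
    "MRComparison",
    "se_from_ci",
    "ci_from_se",
    "expected_effect",
    "observed_effect",
    "altman_bland_test",
    "mr_compare",
    "power_genetic",
]


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Log-odds standard error implied by an odds-ratio confidence interval:
    (ln hi − ln lo) / (2 z)."""
    if ci_low <= 0 or ci_high <= 0:
        raise InvalidParameterError("CI bounds must be positive odds ratios")
    if ci_high < ci_low:
        raise InvalidParameterError("ci_high must be >= ci_low")
    if not 0 < level < 1:
        raise InvalidParameterError("level must lie in (0,1)")
    z = stats.norm.ppf(0.5 + level / 2)
    return float((np.log(ci_high) - np.log(ci_low)) / (2 * z))


def ci_from_se(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Odds-ratio Wald CI from a log-odds estimate; inverse of se_from_ci."""
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def expected_effect(beta_gb: float, or_bd: float) -> tuple[float, float]:
    """Expected per-allele effect on the outcome: the instrument-exposure
    slope (mg/dl per allele) times the log of the exposure-outcome OR per
    mg/dl.  Returns (log-odds, odds ratio)."""
    if or_bd <= 0:
        raise InvalidParameterError("or_bd must be a positive odds ratio")
    log_odds = beta_gb * np.log(or_bd)
    return float(log_odds), float(np.exp(log_odds))


def observed_effect(
    table: pd.DataFrame,
    instrument: str,
    adjustment: AdjustmentSet,
    outcome: str = "nafld_followup",
) -> EffectEstimate:
    """Per-allele (or per-score-unit) logistic log-odds of the outcome on
    the instrument column, under the given adjustment set."""
    df = complete_cases(table, [outcome, instrument, *adjustment.names])
    g = df[instrument].astype(float)
    if g.nunique() < 2:
        raise InvalidParameterError(f"instrument {instrument!r} is degenerate")
    X = pd.concat([g.rename(instrument), build_design(df, adjustment.covariates)], axis=1)
    res = fit_logistic(df[outcome].astype(float), X, f"observed_effect[{instrument}]", focus=instrument)
    beta = float(res.params[instrument])
    se = float(res.bse[instrument])
    return EffectEstimate(
        scale="per_allele",
        beta=beta,
        se=se,
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p=float(res.pvalues[instrument]),
        n=int(len(df)),
    )


def altman_bland_test(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Interaction test between two independent estimates:
    z = (b1 − b2)/√(se1² + se2²), two-sided normal P."""
    if se1 < 0 or se2 < 0:
        raise InvalidParameterError("standard errors must be nonnegative")
    denom = se1**2 + se2**2
    if denom == 0:
        raise InvalidParameterError("both standard errors are zero")
    z = (b1 - b2) / np.sqrt(denom)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass(frozen=True)
class MRComparison:
    """Observed vs expected per-allele effect with the interaction test."""

    instrument: str
    observed: EffectEstimate
    expected_beta: float
    expected_or: float
    expected_se: float
    expected_ci_low: float
    expected_ci_high: float
    z: float
    p: float
    propagation_mode: str


def mr_compare(
    instrument: InstrumentSummary,
    exposure_outcome: EffectEstimate,
    observed: EffectEstimate,
    mode: str = "fixed_expected",
) -> MRComparison:
    """Assemble the expected effect (βGB × ln OR_BD) and compare it with the
    observed per-allele estimate.

    ``fixed_expected`` treats the expected effect as a known constant
    (zero SE, degenerate CI); ``delta_method`` propagates the instrument
    slope's SE as |ln OR_BD| × se(βGB), with the exposure-outcome OR still
    treated as fixed.
    """
    if exposure_outcome.scale != "per_mg_dl":
        raise ScaleMismatchError(
            f"exposure-outcome estimate must be per mg/dl, got {exposure_outcome.scale!r}"
        )
    if not observed.scale.startswith("per_"):
        raise ScaleMismatchError(f"observed estimate must be per allele, got {observed.scale!r}")
    or_bd = exposure_outcome.odds_ratio
    expected_beta, expected_or = expected_effect(instrument.beta, or_bd)
    if mode == "fixed_expected":
        expected_se = 0.0
    elif mode == "delta_method":
        expected_se = abs(np.log(or_bd)) * instrument.se
    else:
        raise InvalidParameterError(f"unknown propagation mode {mode!r}")
    lo, hi = ci_from_se(expected_beta, expected_se) if expected_se > 0 else (expected_or, expected_or)
    z, p = altman_bland_test(observed.beta, observed.se, expected_beta, expected_se)
    return MRComparison(
        instrument=instrument.snp,
        observed=observed,
        expected_beta=float(expected_beta),
        expected_or=float(expected_or),
        expected_se=float(expected_se),
        expected_ci_low=float(lo),
        expected_ci_high=float(hi),
        z=z,
        p=p,
        propagation_mode=mode,
    )


def power_genetic(
    n_cases: int,
    n_controls: int,
    maf: float,
    or_per_allele: float,
    alpha: float = 0.05,
) -> float:
    """Normal-approximation power to detect a per-allele log-odds effect
    under an additive model.

    Uses Var(β̂) ≈ 1/(N φ(1−φ) · 2q(1−q)) with case fraction φ; this is an
    approximation, adequate for planning but not an exact likelihood-based
    calculation.
    """
    if n_cases < 1 or n_controls < 1:
        raise InvalidParameterError("case and control counts must be positive")
    if not 0 < maf < 1:
        raise InvalidParameterError("maf must lie strictly in (0,1)")
    if or_per_allele <= 0:
        raise InvalidParameterError("or_per_allele must be positive")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0,1)")
    n = n_cases + n_controls
    phi = n_cases / n
    var_g = 2 * maf * (1 - maf)
    se = np.sqrt(1.0 / (n * phi * (1 - phi) * var_g))
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    delta = abs(np.log(or_per_allele)) / se
    power = stats.norm.sf(z_alpha - delta) + stats.norm.cdf(-z_alpha - delta)
    return float(power)
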