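"""Shared regression plumbing: design matrices, guarded GLM fits."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import FitError, SeparationError

Z95 = 1.959964  # two-sided 95% normal quantile, carried unrounded


def complete_cases(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Complete-case subset on the listed columns (per-model, mirroring the
    removal of records with missing key fields)."""
    return df.dropna(subset=[c for c in cols if c in df.columns])


def build_design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Expand covariates to numeric columns; categoricals become indicator
    columns named ``name[level]`` with the reference level dropped."""
    pieces = []
    for cov in covariates:
        col = df[cov.name]
        if cov.kind == "continuous":
            pieces.append(col.astype(float).rename(cov.name))
        elif cov.kind == "categorical":
            levels = sorted(col.dropna().unique(), key=str)
            ref = cov.reference if cov.reference is not None else levels[0]
            for level in levels:
                if level == ref:
                    continue
                pieces.append(
                    (col == level).astype(float).rename(f"{cov.name}[{level}]")
                )
        else:
            raise ValueError(f"unknown covariate kind {cov.kind!r}")
    if not pieces:
        return pd.DataFrame(index=df.index)
    X = pd.concat(pieces, axis=1)
    # a covariate can go constant inside a small stratum; keeping it would
    # make the design singular (collinear with the intercept)
    keep = [c for c in X.columns if X[c].nunique(dropna=True) > 1]
    return X[keep]


def fit_logistic(y: pd.Series, X: pd.DataFrame, model_name: str, focus=None):
    """Maximum-likelihood logistic fit with explicit separation handling.

    ``focus`` names the column(s) whose estimates will be reported; the
    quasi-separation check is restricted to them (plus the constant-outcome
    check), so a sparse nuisance dummy with a flat likelihood direction does
    not abort an otherwise well-identified fit.  With ``focus=None`` every
    coefficient is checked.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError(model_name, "outcome is constant")
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", category=RuntimeWarning)
            model = sm.Logit(y, Xc)
            try:
                res = model.fit(disp=0, maxiter=200, warn_convergence=False)
                newton_failed = not res.mle_retvals.get("converged", True)
            except np.linalg.LinAlgError:
                # Newton's Hessian can collapse on quasi-separated sparse
                # dummies even when the design has full rank
                newton_failed = True
            if newton_failed:
                res = model.fit(disp=0, method="bfgs", maxiter=2000, warn_convergence=False)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(model_name, str(exc)) from exc
    except Exception as exc:  # singular design, etc.
        raise FitError(model_name, str(exc)) from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError(model_name, "did not converge")
    # quasi-separation slips past statsmodels' check; huge SEs betray it
    checked = list(X.columns) if focus is None else ([focus] if isinstance(focus, str) else list(focus))
    params = res.params[checked]
    bse = res.bse[checked]
    if np.any(np.abs(params) > 30) or np.any(bse > 100):
        raise SeparationError(model_name, "quasi-complete separation (degenerate fit)")
    return res


def fit_ols(y: pd.Series, X: pd.DataFrame, model_name: str):
    yv = np.asarray(y, dtype=float)
    if np.var(yv) == 0:
        raise FitError(model_name, "outcome has zero variance")
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        return sm.OLS(yv, Xc).fit()
    except Exception as exc:
        raise FitError(model_name, str(exc)) from exc
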