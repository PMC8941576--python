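"""Instrument validation for the two uric-acid SNPs: Hardy–Weinberg
testing, genotype coding, per-allele exposure regressions, variance
explained, the unweighted allele score, and confounder-balance checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._modeling import Z95, build_design, complete_cases, fit_ols
from .errors import (
    DegenerateInstrumentError,
    InvalidParameterError,
)
from .observational_association import AdjustmentSet, Covariate

__all__ = [
    "GenotypeRecord",
    "InstrumentSummary",
    "hwe_test",
    "code_genotypes",
    "fit_instrument",
    "build_genetic_score",
    "confounder_balance",
    "read_genotypes_vcf",
]


@dataclass(frozen=True)
class GenotypeRecord:
    """Risk-allele counts for one participant; ``None`` marks a no-call."""

    participant_id: str
    snp1: Optional[int]
    snp2: Optional[int]

    def __post_init__(self):
        for v in (self.snp1, self.snp2):
            if v is not None and v not in (0, 1, 2):
                raise InvalidParameterError(f"allele count must be 0/1/2, got {v}")


@dataclass(frozen=True)
class InstrumentSummary:
    """Per-allele effect of one SNP (or score) on the exposure, with QC."""

    snp: str
    beta: float  # mg/dl per allele
    se: float
    ci_low: float
    ci_high: float
    p: float
    variance_explained: float
    hwe_chi2: Optional[float]
    hwe_p: Optional[float]
    call_rate: float
    n: int


def hwe_test(counts: Iterable[int]) -> tuple[float, float]:
    """1-df Pearson chi-square of observed genotype counts (n0, n1, n2)
    against Hardy–Weinberg expectations at the sample allele frequency."""
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0:
        raise InvalidParameterError("genotype counts must be nonnegative")
    n = n0 + n1 + n2
    if n == 0:
        raise InvalidParameterError("all genotype counts are zero")
    q = (n1 + 2 * n2) / (2 * n)  # sample risk-allele frequency
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def code_genotypes(counts, model: str = "additive"):
    """Recode allele counts under an inheritance model.

    additive → counts 0/1/2; dominant → carrier indicator; codominant →
    two indicator columns (het, rare_hom) with common-hom reference.
    Missing counts propagate as missing.
    """
    s = pd.Series(counts, dtype="Float64")
    bad = s.dropna()[~s.dropna().isin([0, 1, 2])]
    if len(bad):
        raise InvalidParameterError(f"allele counts must be 0/1/2, got {bad.unique()}")
    if model == "additive":
        return s.astype(float)
    if model == "dominant":
        return (s >= 1).astype(float).where(s.notna())
    if model == "codominant":
        return pd.DataFrame(
            {
                "het": (s == 1).astype(float).where(s.notna()),
                "rare_hom": (s == 2).astype(float).where(s.notna()),
            }
        )
    raise InvalidParameterError(f"unknown genetic model {model!r}")


def _merged(table: pd.DataFrame, genotypes: pd.DataFrame) -> pd.DataFrame:
    return table.merge(genotypes, on="participant_id", how="inner")


def fit_instrument(
    table: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp: str,
    adjustment: AdjustmentSet,
    exposure: str = "sua",
    hwe_in_outcome_free: bool = True,
    variance_mode: str = "partial",
) -> InstrumentSummary:
    """Linear regression of the exposure (mg/dl) on the additive allele
    count plus covariates.

    ``variance_explained`` is the squared partial correlation of the
    genotype term (``variance_mode="partial"``) or the marginal R² of a
    genotype-only fit (``"marginal"``).  Hardy–Weinberg is evaluated among
    outcome-free participants when an outcome column is available.
    """
    df = _merged(table, genotypes)
    call_rate = float(df[snp].notna().mean()) if len(df) else 0.0
    df = complete_cases(df, [exposure, snp, *adjustment.names])
    g = df[snp].astype(float)
    if g.nunique() < 2:
        raise DegenerateInstrumentError(f"{snp} is monomorphic in the analyzed records")

    X = pd.concat([g.rename(snp), build_design(df, adjustment.covariates)], axis=1)
    res = fit_ols(df[exposure], X, f"instrument[{snp}]")
    beta = float(res.params[snp])
    se = float(res.bse[snp])
    t = float(res.tvalues[snp])
    if variance_mode == "partial":
        var_exp = t**2 / (t**2 + res.df_resid)
    elif variance_mode == "marginal":
        res0 = fit_ols(df[exposure], g.to_frame(), f"instrument_marginal[{snp}]")
        var_exp = float(res0.rsquared)
    else:
        raise InvalidParameterError(f"unknown variance_mode {variance_mode!r}")

    hwe_chi2 = hwe_p = None
    hwe_df = df
    if hwe_in_outcome_free and "nafld_followup" in df.columns:
        free = df["nafld_followup"].fillna(1) == 0
        if free.any():
            hwe_df = df.loc[free]
    counts = [(hwe_df[snp] == k).sum() for k in (0, 1, 2)]
    if sum(counts) > 0:
        hwe_chi2, hwe_p = hwe_test(counts)

    return InstrumentSummary(
        snp=snp,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        p=float(res.pvalues[snp]),
        variance_explained=float(var_exp),
        hwe_chi2=hwe_chi2,
        hwe_p=hwe_p,
        call_rate=call_rate,
        n=int(len(df)),
    )


def build_genetic_score(genotypes: pd.DataFrame, snps: tuple[str, str] = ("snp1", "snp2")) -> pd.Series:
    """Unweighted count of risk alleles across the SNPs (0..4); missing
    either SNP yields a missing score."""
    cols = [pd.Series(genotypes[s], dtype="Float64") for s in snps]
    score = cols[0] + cols[1]
    return score.rename("genetic_score")


def confounder_balance(
    table: pd.DataFrame,
    genotypes: pd.DataFrame,
    covariates: tuple[Covariate, ...],
    snp: str = "snp1",
) -> pd.DataFrame:
    """Association of each candidate confounder with the additive allele
    count: linear regression for continuous covariates, Pearson chi-square
    of the covariate × genotype contingency table for categorical ones.

    Constant covariates are skipped with a warning entry rather than an
    error.  Returns a tidy table (covariate, kind, statistic, p, note).
    """
    df = _merged(table, genotypes)
    rows = []
    for cov in covariates:
        sub = complete_cases(df, [cov.name, snp])
        g = sub[snp].astype(float)
        x = sub[cov.name]
        if x.nunique(dropna=True) < 2:
            rows.append((cov.name, cov.kind, np.nan, np.nan, "constant covariate, skipped"))
            continue
        if cov.kind == "continuous":
            lr = stats.linregress(g.to_numpy(), x.astype(float).to_numpy())
            tstat = lr.slope / lr.stderr if lr.stderr > 0 else np.inf  # exact fit
            rows.append((cov.name, cov.kind, float(tstat), float(lr.pvalue), ""))
        else:
            tab = pd.crosstab(x, g)
            chi2, p, _, _ = stats.chi2_contingency(tab)
            rows.append((cov.name, cov.kind, float(chi2), float(p), ""))
    return pd.DataFrame(rows, columns=["covariate", "kind", "statistic", "p", "note"])


def read_genotypes_vcf(path, snp_ids: tuple[str, str]) -> pd.DataFrame:
    """Minimal VCF import: diploid GT calls of the two named sites, summed
    to alternate-allele counts; phased or unphased separators accepted,
    missing calls become missing counts."""
    samples: list[str] = []
    calls: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            vid = fields[2]
            if vid not in snp_ids:
                continue
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise InvalidParameterError(f"site {vid} has no GT field") from None
            counts = []
            for entry in fields[9:]:
                gt = entry.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    counts.append(np.nan)
                else:
                    counts.append(sum(int(a) > 0 for a in alleles))
            calls[vid] = counts
    missing = [s for s in snp_ids if s not in calls]
    if missing:
        raise InvalidParameterError(f"sites not found in VCF: {missing}")
    return pd.DataFrame(
        {
            "participant_id": samples,
            "snp1": pd.array(calls[snp_ids[0]], dtype="Float64"),
            "snp2": pd.array(calls[snp_ids[1]], dtype="Float64"),
        }
    )
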