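"""Seeded synthetic cohorts with the statistical structure the analysis
assumes.

Two scenarios are supported.  Under ``causal`` the uric-acid level enters
the outcome log-odds directly with a configurable per-mg/dl odds ratio.
Under ``marker`` the direct coefficient is exactly zero and the entire
exposure–outcome association is driven by a shared latent metabolic
confounder, so genotype-based analyses should see a null effect — the
dissociation the triangulation is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .errors import InvalidParameterError
from .observational_association import AdjustmentSet, Covariate

__all__ = [
    "SimulationConfig",
    "generate_genotypes",
    "generate_cohort",
    "generating_adjustment",
    "write_cohort_csv",
    "write_genotypes_csv",
    "read_cohort_csv",
    "read_genotypes_csv",
]

# Marginals emulating the source population (age/BMI/female fraction etc.).
_AGE_MEAN, _AGE_SD = 61.7, 7.8
_BMI_MEAN, _BMI_SD = 23.3, 2.8
_FPG_MEAN, _FPG_SD = 5.8, 1.3
_CRE_MEAN, _CRE_SD = 80.0, 20.0
_SUA_FLOOR = 0.5  # mg/dl, keeps labs physiologic after noise


def _default_confounders() -> dict:
    # name -> (effect on SUA in mg/dl per unit, effect on NAFLD log-odds per unit)
    return {
        "bmi": (0.10, 0.12),
        "age": (0.012, 0.015),
        "fpg": (0.04, 0.10),
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; every field is addressable from YAML."""

    n: int = 8429
    seed: int = 0
    maf_1: float = 0.44  # plausible East-Asian frequencies, configurable
    maf_2: float = 0.29
    beta_allele_1: float = 0.19  # mg/dl per risk allele
    beta_allele_2: float = 0.22
    sua_mean_male: float = 5.3
    sua_mean_female: float = 4.2
    sua_sd: float = 1.2  # residual noise; each SNP then explains ~1% of variance
    scenario: str = "causal"  # causal | marker
    or_per_mgdl: float = 1.18  # used only under causal
    confounder_effects: dict = field(default_factory=_default_confounders)
    baseline_prevalence: float = 0.238
    marker_latent_sd: float = 0.8  # latent confounder SD (mg/dl on the SUA scale)
    marker_latent_logodds: float = 0.5  # latent loading on the outcome log-odds
    female_fraction: float = 0.56
    nuisance_flag_rate: float = 0.0  # hepatitis/cirrhosis/HBsAg/med flags

    def __post_init__(self):
        if self.n < 1:
            raise InvalidParameterError("n must be >= 1")
        for name in ("maf_1", "maf_2", "baseline_prevalence", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidParameterError(f"{name} must lie strictly in (0,1), got {v}")
        if not self.sua_sd > 0:
            raise InvalidParameterError("sua_sd must be positive")
        if self.scenario not in ("causal", "marker"):
            raise InvalidParameterError(f"scenario must be causal|marker, got {self.scenario!r}")
        if self.or_per_mgdl <= 0:
            raise InvalidParameterError("or_per_mgdl must be positive")
        if not 0.0 <= self.nuisance_flag_rate < 1.0:
            raise InvalidParameterError("nuisance_flag_rate must be in [0,1)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "confounder_effects" in d:
            d["confounder_effects"] = {
                k: tuple(v) for k, v in d["confounder_effects"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confounder_effects"] = {k: list(v) for k, v in d["confounder_effects"].items()}
        return d


def generate_genotypes(
    n: int, maf: float, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Risk-allele counts in {0,1,2} drawn at Hardy–Weinberg proportions
    ((1−q)², 2q(1−q), q²) for risk-allele frequency q."""
    if not 0.0 < maf < 1.0:
        raise InvalidParameterError(f"maf must lie strictly in (0,1), got {maf}")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    q = maf
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    return rng.choice(3, size=n, p=probs).astype(np.int64)


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    f = lambda b0: float(np.mean(expit(b0 + eta))) - prevalence
    return brentq(f, -30.0, 30.0)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (cohort table, genotype table) under the configured scenario.

    SUA = sex-specific mean + Σ βk·Gk + Σ confounder effects + latent (marker
    scenario) + Gaussian noise, floored at 0.5 mg/dl.  The outcome intercept
    is calibrated so the marginal incidence equals ``baseline_prevalence``.
    Hepatic markers ALT/AST/GGT are lognormal with means shifting with
    outcome status and SUA; PLT is normal, slightly lower in cases.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    sex = np.where(rng.random(n) < cfg.female_fraction, "female", "male")
    female = sex == "female"
    age = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, n), 35.0, 95.0)
    bmi = np.clip(rng.normal(_BMI_MEAN, _BMI_SD, n), 14.0, 45.0)
    waist = np.clip(rng.normal(80.0, 8.6, n) + 1.2 * (bmi - _BMI_MEAN), 50.0, None)
    fpg = np.clip(rng.normal(_FPG_MEAN, _FPG_SD, n), 2.5, None)
    cre = np.clip(rng.normal(_CRE_MEAN, _CRE_SD, n) + np.where(female, -8.0, 8.0), 20.0, None)

    # lifestyle: men smoke/drink far more in this population
    def _cat3(p_current, p_quit):
        u = rng.random(n)
        return np.where(u < p_current, "current", np.where(u < p_current + p_quit, "quit", "never"))

    smoking = np.where(female, _cat3(0.03, 0.02), _cat3(0.35, 0.22))
    drinking = np.where(female, _cat3(0.04, 0.02), _cat3(0.40, 0.12))
    physical_activity = (rng.random(n) < 0.90).astype(int)
    history_hypertension = (rng.random(n) < 0.31).astype(int)
    history_chd = (rng.random(n) < 0.13).astype(int)
    history_diabetes = (rng.random(n) < 0.10).astype(int)
    glucose_lowering_med = ((rng.random(n) < 0.4) & (history_diabetes == 1)).astype(int)
    alcohol_gpw = np.where(
        drinking == "current", rng.gamma(2.0, 40.0, n), np.where(drinking == "quit", rng.gamma(1.5, 10.0, n), 0.0)
    )

    g1 = generate_genotypes(n, cfg.maf_1, rng=rng)
    g2 = generate_genotypes(n, cfg.maf_2, rng=rng)

    conf_cols = {"bmi": bmi, "age": age, "fpg": fpg, "cre": cre, "waist": waist}
    sua_conf = np.zeros(n)
    logit_conf = np.zeros(n)
    for name, (eff_sua, eff_logodds) in cfg.confounder_effects.items():
        if name not in conf_cols:
            raise InvalidParameterError(f"unknown confounder {name!r}")
        centered = conf_cols[name] - conf_cols[name].mean()
        sua_conf += eff_sua * centered
        logit_conf += eff_logodds * centered

    latent = rng.normal(0.0, cfg.marker_latent_sd, n) if cfg.scenario == "marker" else np.zeros(n)

    sua_mean = np.where(female, cfg.sua_mean_female, cfg.sua_mean_male)
    sua = (
        sua_mean
        + cfg.beta_allele_1 * g1
        + cfg.beta_allele_2 * g2
        + sua_conf
        + latent
        + rng.normal(0.0, cfg.sua_sd, n)
    )
    sua = np.maximum(sua, _SUA_FLOOR)

    if cfg.scenario == "causal":
        eta = np.log(cfg.or_per_mgdl) * sua + logit_conf
    else:  # marker: direct SUA coefficient exactly 0
        eta = logit_conf + cfg.marker_latent_logodds * latent
    intercept = _calibrate_intercept(eta, cfg.baseline_prevalence)
    nafld = (rng.random(n) < expit(intercept + eta)).astype(int)

    sua_c = sua - sua.mean()
    alt = np.exp(rng.normal(np.log(16.0) + 0.28 * nafld + 0.06 * sua_c, 0.45, n))
    ast = np.exp(rng.normal(np.log(21.0) + 0.14 * nafld + 0.025 * sua_c, 0.33, n))
    ggt = np.exp(rng.normal(np.log(24.0) + 0.36 * nafld + 0.08 * sua_c, 0.55, n))
    plt = np.clip(rng.normal(215.0, 52.0, n) - 10.0 * nafld, 50.0, None)

    tg = np.clip(rng.normal(1.2, 0.7, n) + 0.35 * nafld, 0.2, None)
    tc = np.clip(rng.normal(5.1, 0.95, n), 2.0, None)
    hdl = np.clip(rng.normal(1.46, 0.4, n) - 0.1 * nafld, 0.4, None)
    ldl = np.clip(rng.normal(3.0, 0.8, n), 0.5, None)

    r = cfg.nuisance_flag_rate
    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "waist": waist,
            "smoking": smoking,
            "drinking": drinking,
            "physical_activity": physical_activity,
            "history_diabetes": history_diabetes,
            "history_chd": history_chd,
            "history_hypertension": history_hypertension,
            "glucose_lowering_med": glucose_lowering_med,
            "sua_lowering_med": (rng.random(n) < r).astype(int),
            "nafld_assoc_med": (rng.random(n) < r).astype(int),
            "chronic_hepatitis": (rng.random(n) < r).astype(int),
            "cirrhosis": (rng.random(n) < r / 10).astype(int),
            "hbsag_positive": (rng.random(n) < r).astype(int),
            "alcohol_gpw": alcohol_gpw,
            "sua": sua,
            "alt": alt,
            "ast": ast,
            "ggt": ggt,
            "plt": plt,
            "fpg": fpg,
            "cre": cre,
            "tg": tg,
            "tc": tc,
            "hdl": hdl,
            "ldl": ldl,
            "ultrasound_done_baseline": 1,
            "ultrasound_done_followup": 1,
            "nafld_baseline": 0,
            "nafld_followup": nafld,
            "latent_confounder": latent,  # simulation-internal, for diagnostics
        }
    )
    genotypes = pd.DataFrame(
        {"participant_id": cohort["participant_id"], "snp1": g1, "snp2": g2}
    )
    return cohort, genotypes


def generating_adjustment(config: Optional[SimulationConfig] = None) -> AdjustmentSet:
    """Adjustment set containing exactly the confounders the generator wires
    into both the exposure and the outcome (plus sex, which shifts the
    exposure mean).  This is the correctly specified model for
    parameter-recovery checks."""
    effects = config.confounder_effects if config is not None else _default_confounders()
    covs = tuple(Covariate(name) for name in effects) + (
        Covariate("sex", "categorical", reference="male"),
    )
    return AdjustmentSet("generating_confounders", covs)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")


def write_genotypes_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path, column_map: Optional[dict] = None) -> pd.DataFrame:
    """Read a cohort CSV; ``column_map`` renames foreign headers onto the
    canonical ones (e.g. {"uric_acid": "sua"})."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return df


def read_genotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "snp1", "snp2"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"genotype CSV missing columns: {sorted(missing)}")
    return df
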