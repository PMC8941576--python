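import pandas as pd
import pytest

from suamr import cohort_core
from suamr.synthetic_cohort import (
    SimulationConfig,
    generate_cohort,
    generating_adjustment,
)


@pytest.fixture(scope="session")
def causal_cohort():
    """One large causal-scenario cohort with derived columns, plus genotypes."""
    cohort, geno = generate_cohort(SimulationConfig(n=8429, seed=11))
    return cohort_core.add_derived_columns(cohort), geno


@pytest.fixture(scope="session")
def marker_cohort():
    cohort, geno = generate_cohort(SimulationConfig(n=8429, seed=12, scenario="marker"))
    return cohort_core.add_derived_columns(cohort), geno


@pytest.fixture(scope="session")
def merged_causal(causal_cohort):
    df, geno = causal_cohort
    merged = df.merge(geno, on="participant_id")
    merged["genetic_score"] = merged["snp1"] + merged["snp2"]
    return merged


@pytest.fixture(scope="session")
def conf_adj():
    """The generator's correctly specified confounder adjustment set."""
    return generating_adjustment()


def make_clean_table(n: int = 10) -> pd.DataFrame:
    """A tiny cohort table that passes every exclusion criterion."""
    return pd.DataFrame(
        {
            "participant_id": [f"X{i}" for i in range(n)],
            "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
            "age": 60.0,
            "bmi": 23.0,
            "smoking": "never",
            "drinking": "never",
            "alcohol_gpw": 0.0,
            "sua": 5.0,
            "chronic_hepatitis": 0,
            "cirrhosis": 0,
            "hbsag_positive": 0,
            "nafld_assoc_med": 0,
            "sua_lowering_med": 0,
            "ultrasound_done_baseline": 1,
            "ultrasound_done_followup": 1,
            "nafld_baseline": 0,
            "nafld_followup": 0,
        }
    )
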