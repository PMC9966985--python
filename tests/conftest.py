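import numpy as np
import pandas as pd
import pytest

from gcompsurv import GeneratorConfig, generate_cohort, study_config, transform_exposures


@pytest.fixture(scope="session")
def small_cohort():
    """Study-like synthetic cohort, small enough for fast unit tests."""
    return generate_cohort(study_config(n_subjects=1500, seed=123))


@pytest.fixture(scope="session")
def small_transformed(small_cohort):
    return transform_exposures(small_cohort)


@pytest.fixture()
def tiny_cohort():
    """Hand-built 4-subject cohort exercising the canonical columns."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4],
            "blood_lead": [4.0, 1.0, 8.0, 2.0],
            "urinary_cadmium": [0.8, 0.2, 1.6, 0.4],
            "urinary_creatinine": [2.0, 1.0, 0.8, 1.0],
            "age": [30.0, 50.0, 70.0, 40.0],
            "sex": ["male", "female", "female", "male"],
            "race_ethnicity": ["white"] * 4,
            "poverty_tertile": [1, 2, 3, 1],
            "education_years": [12.0, 10.0, 8.0, 16.0],
            "residence": ["metro", "metro", "non_metro", "metro"],
            "smoking": ["never", "current", "former", "never"],
            "bmi": [24.0, 28.0, 31.0, 22.0],
            "physical_activity": ["high", "none", "low", "high"],
            "diet_index": [0.1, -0.5, 0.3, 0.0],
            "weight": [1.0, 2.0, 0.5, 1.5],
            "followup_years": [2.4, 27.0, 12.0, 5.5],
            "status": ["dead", "alive", "dead", "alive"],
            "cause": ["cvd", "none", "cancer", "none"],
        }
    )


def saturated_fixture():
    """20-subject single-period cohort with binary exposure and covariate.

    Cell event fractions (1/5, 2/5, 3/5, 4/5) are chosen so their empirical
    log-odds are exactly additive in exposure and covariate — the
    no-interaction logistic model then reproduces the cell fractions
    exactly, making model-based g-computation comparable to exhaustive
    nonparametric standardization with zero approximation error.
    """
    rows = []
    cells = [  # (lead value, sex, n, events):  lead 1.0 -> log2 = 0, 2.0 -> 1
        (1.0, "female", 5, 1),
        (2.0, "female", 5, 2),
        (1.0, "male", 5, 3),
        (2.0, "male", 5, 4),
    ]
    i = 0
    for lead, sex, n, k in cells:
        for j in range(n):
            i += 1
            rows.append(
                {
                    "id": i,
                    "blood_lead": lead,
                    "cadmium_std": 0.5,
                    "urinary_cadmium": 0.5,
                    "urinary_creatinine": 1.0,
                    "sex": sex,
                    "weight": 1.0,
                    "followup_years": 1.0,
                    "status": "dead" if j < k else "alive",
                    "cause": "other" if j < k else "none",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def saturated_cohort():
    return saturated_fixture()
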