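import datetime as dt

import numpy as np
import pandas as pd
import pytest

from labconcord.synthetic_ehr import InstitutionConfig, OutcomeMix, SimulationConfig

OUTCOMES = (
    "aki",
    "hyperkalemia",
    "hypoglycemia",
    "hyponatremia",
    "anemia",
    "neutropenia",
    "thrombocytopenia",
)


def make_sim_config(
    n_patients: int = 300,
    intercept_sd: float = 1.0,
    sens: tuple[float, float, float] = (0.25, 0.35, 0.45),
    sens_b: tuple[float, float, float] | None = None,
    fpr: float = 0.01,
    fpr_b: float | None = None,
    testing_prob: float = 0.6,
    prevalence: tuple[float, float, float, float] = (0.88, 0.06, 0.04, 0.02),
    unit_acuity_sd: float = 0.0,
    unit_coding_shift_sd: float = 0.0,
    unit_coding_shift_sd_b: float | None = None,
    seed: int = 0,
) -> SimulationConfig:
    """Two-site config builder with identical outcome mixes everywhere
    unless site_b overrides are given."""

    def site(name, s, f, shift):
        return InstitutionConfig(
            name=name,
            n_patients=n_patients,
            testing_prob_per_day={a: testing_prob for a in
                                  ("creatinine", "potassium", "glucose", "sodium",
                                   "anc", "hemoglobin", "platelets")},
            outcomes={
                oc: OutcomeMix(
                    prevalence=prevalence,
                    coding_sensitivity=s,
                    false_positive_rate=f,
                )
                for oc in OUTCOMES
            },
            unit_acuity_sd=unit_acuity_sd,
            unit_coding_shift_sd=shift,
        )

    return SimulationConfig(
        institutions=(
            site("site_a", sens, fpr, unit_coding_shift_sd),
            site(
                "site_b",
                sens_b or sens,
                fpr if fpr_b is None else fpr_b,
                unit_coding_shift_sd if unit_coding_shift_sd_b is None
                else unit_coding_shift_sd_b,
            ),
        ),
        intercept_sd=intercept_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded two-site cohort shared by read-only tests."""
    from labconcord import generate_cohort

    return generate_cohort(make_sim_config(n_patients=400, seed=11))


@pytest.fixture
def tiny_tables():
    """Three admissions, five measurements, hand-written flat tables."""
    admissions = pd.DataFrame(
        {
            "admission_id": ["a1", "a2", "a3"],
            "patient_id": ["p1", "p1", "p2"],
            "institution": ["site_a", "site_a", "site_b"],
            "admit_date": ["2019-01-01", "2020-05-02", "2021-07-03"],
            "discharge_date": ["2019-01-04", "2020-05-03", "2021-07-10"],
            "age_at_admission": [200, 700, 4000],
            "sex": ["female", "female", "male"],
            "died_in_hospital": [False, False, True],
        }
    )
    measurements = pd.DataFrame(
        {
            "admission_id": ["a1", "a1", "a2", "a3", "a3"],
            "analyte": ["glucose", "sodium", "glucose", "hemoglobin", "platelets"],
            "value": [4.9, 138.0, 2.5, 80.0, 40.0],
            "unit": ["mmol/L", "mmol/L", "mmol/L", "g/L", "10^9/L"],
            "collected_at": ["2019-01-01T08:00:00"] * 2
            + ["2020-05-02T09:00:00", "2021-07-04T07:30:00", "2021-07-05T07:30:00"],
        }
    )
    diagnoses = pd.DataFrame(
        {
            "admission_id": ["a2", "a3"],
            "code": ["E16.2", "D69.6"],
            "vocabulary": ["ICD10", "ICD10"],
        }
    )
    unit_stays = pd.DataFrame(
        {"admission_id": ["a1", "a1", "a2", "a3"], "unit_id": ["u1", "u2", "u1", "u3"]}
    )
    from labconcord.labeling import default_reference_ranges

    return {
        "admissions": admissions,
        "measurements": measurements,
        "diagnoses": diagnoses,
        "unit_stays": unit_stays,
        "reference_ranges": default_reference_ranges(),
    }
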