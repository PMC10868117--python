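import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from labconcord.data_model import CohortBundle
from labconcord.labeling import (
    LabelingError,
    SeverityThresholds,
    UnitError,
    admission_extremum,
    default_outcome_definitions,
    default_reference_ranges,
    diagnosis_label,
    label_cohort,
    normalize_measurements,
    normalize_unit,
    severity_labels,
    abnormal_label,
)

DEFS = {d.outcome: d for d in default_outcome_definitions()}


@pytest.mark.parametrize(
    "value, unit, analyte, expected, tol",
    [
        (10.0, "g/dL", "hemoglobin", 100.0, 1e-9),
        (1.0, "mg/dL", "creatinine", 88.4, 0.1),  # molar mass 113.12 g/mol
        (4.5, "mEq/L", "potassium", 4.5, 1e-9),
        (90.0, "mg/dL", "glucose", 4.996, 0.01),
        (1500.0, "cells/uL", "anc", 1.5, 1e-9),
    ],
)
def test_unit_normalization(value, unit, analyte, expected, tol):
    assert normalize_unit(value, unit, analyte) == pytest.approx(expected, abs=tol)


def test_unrecognized_unit_names_analyte_and_unit():
    with pytest.raises(UnitError, match=r"furlongs.*potassium|potassium.*furlongs"):
        normalize_unit(1.0, "furlongs", "potassium")


def test_admission_extremum_max_min_and_missing():
    meas = pd.DataFrame(
        {"analyte": ["creatinine"] * 3 + ["glucose"], "value": [40.0, 95.0, 60.0, 5.1]}
    )
    assert admission_extremum(meas, DEFS["aki"]) == 95.0
    assert admission_extremum(meas, DEFS["hypoglycemia"]) == 5.1
    assert np.isnan(admission_extremum(meas, DEFS["hyponatremia"]))


@pytest.mark.parametrize(
    "extremum, expected",
    [
        (1.5, (True, True, True)),
        (2.5, (True, True, False)),
        (3.5, (True, False, False)),
        (3.9, (False, False, False)),  # strict inequality at the cutoff
        (float("nan"), (False, False, False)),
    ],
)
def test_severity_labels_glucose_cutoffs(extremum, expected):
    t = SeverityThresholds(3.9, 3.0, 2.2)
    assert severity_labels(extremum, t, "below") == expected


def test_severity_labels_above_direction():
    t = SeverityThresholds(5.5, 6.0, 6.5)
    assert severity_labels(6.2, t, "above") == (True, True, False)
    assert severity_labels(5.5, t, "above") == (False, False, False)


def test_threshold_ordering_enforced():
    with pytest.raises(LabelingError, match="non-increasing"):
        SeverityThresholds(2.2, 3.0, 3.9).validate("below")


def test_abnormal_label_is_one_sided():
    assert abnormal_label(80.0, 110.0, 160.0, "below") is True
    assert abnormal_label(4.0, 3.5, 5.5, "above") is False
    # value above the high bound does NOT trigger a below-direction label
    assert abnormal_label(180.0, 110.0, 160.0, "below") is False
    assert abnormal_label(float("nan"), 110.0, 160.0, "below") is False


def test_diagnosis_label_prefix_exact_and_idempotence():
    cs = DEFS["aki"].code_set  # prefix N17
    rec = pd.DataFrame({"code": ["N17.9"], "vocabulary": ["ICD10"]})
    assert diagnosis_label(rec, cs) is True
    assert diagnosis_label(rec.iloc[:0], cs) is False
    dup = pd.concat([rec, rec], ignore_index=True)
    assert diagnosis_label(dup, cs) is True
    miss = pd.DataFrame({"code": ["E11.9"], "vocabulary": ["ICD10"]})
    assert diagnosis_label(miss, cs) is False


def _mini_bundle(measurements, diagnoses=None):
    adm = pd.DataFrame(
        {
            "admission_id": ["a1", "a2"],
            "patient_id": ["p1", "p2"],
            "institution": ["site_a", "site_a"],
            "admit_date": ["2020-01-01", "2020-01-01"],
            "discharge_date": ["2020-01-03", "2020-01-03"],
            "age_at_admission": [400, 400],  # toddler
            "sex": ["female", "male"],
            "died_in_hospital": [False, False],
        }
    )
    if diagnoses is None:
        diagnoses = pd.DataFrame(columns=["admission_id", "code", "vocabulary"])
    return CohortBundle(
        admissions=adm,
        measurements=measurements,
        diagnoses=diagnoses,
        unit_stays=pd.DataFrame(columns=["admission_id", "unit_id"]),
        reference_ranges=default_reference_ranges(),
    )


def test_label_cohort_cardinality_and_null_case():
    meas = pd.DataFrame(
        {
            "admission_id": ["a1", "a2"],
            "analyte": ["glucose", "sodium"],
            "value": [5.0, 140.0],  # mid-normal
            "unit": ["mmol/L", "mmol/L"],
            "collected_at": ["2020-01-01T08:00:00"] * 2,
        }
    )
    labels = label_cohort(_mini_bundle(meas), list(DEFS.values()))
    assert len(labels) == 2 * 7
    flags = labels[["lab_abnormal", "lab_mild", "lab_moderate", "lab_severe", "diagnosis_positive"]]
    assert not flags.any().any()


def test_label_cohort_matches_hand_computed_matrix():
    """Values straddling each glucose/hemoglobin cutoff give exactly the
    hand-derived label matrix; AKI uses age-specific relative cutoffs."""
    meas = pd.DataFrame(
        {
            "admission_id": ["a1", "a1", "a2", "a2"],
            "analyte": ["glucose", "hemoglobin", "glucose", "creatinine"],
            # a1: glucose 2.5 (mild+moderate), hgb 60 (all three + abnormal)
            # a2: glucose 4.0 (negative), creatinine 85 = 2.125x toddler high 40
            "value": [2.5, 60.0, 4.0, 85.0],
            "unit": ["mmol/L", "g/L", "mmol/L", "umol/L"],
            "collected_at": ["2020-01-01T08:00:00"] * 4,
        }
    )
    diag = pd.DataFrame(
        {"admission_id": ["a2"], "code": ["N17.0"], "vocabulary": ["ICD10"]}
    )
    labels = label_cohort(_mini_bundle(meas, diag), list(DEFS.values()))
    idx = labels.set_index(["admission_id", "outcome"])

    def row(adm, oc):
        r = idx.loc[(adm, oc)]
        return (
            bool(r["lab_abnormal"]),
            bool(r["lab_mild"]),
            bool(r["lab_moderate"]),
            bool(r["lab_severe"]),
            bool(r["diagnosis_positive"]),
        )

    assert row("a1", "hypoglycemia") == (True, True, True, False, False)
    assert row("a1", "anemia") == (True, True, True, True, False)
    assert row("a2", "hypoglycemia") == (False, False, False, False, False)
    # creatinine 85 vs toddler cutoffs 60 / 80 / 120 (1.5x, 2x, 3x of 40)
    assert row("a2", "aki") == (True, True, True, False, True)
    # unmeasured analyte: negative lab labels, admission still present
    assert row("a1", "thrombocytopenia") == (False, False, False, False, False)


def test_nesting_invariant_on_simulated_cohorts(small_cohort):
    bundle, _ = small_cohort
    labels = label_cohort(bundle, list(DEFS.values()))
    for _, sub in labels.groupby("outcome"):
        assert sub["lab_severe"].sum() <= sub["lab_moderate"].sum() <= sub["lab_mild"].sum()


def test_tightening_a_below_cutoff_never_adds_positives(small_cohort):
    bundle, _ = small_cohort
    base = DEFS["hypoglycemia"]
    loose = label_cohort(bundle, [base])
    tight_def = type(base)(
        outcome=base.outcome,
        analyte=base.analyte,
        direction=base.direction,
        thresholds=SeverityThresholds(3.0, 2.5, 2.0),
        code_set=base.code_set,
        default_code=base.default_code,
    )
    tight = label_cohort(bundle, [tight_def])
    for col in ("lab_mild", "lab_moderate", "lab_severe"):
        assert tight[col].sum() <= loose[col].sum()
        assert not (tight[col] & ~loose[col]).any()


def test_labeling_invariant_to_storage_units(small_cohort):
    bundle, _ = small_cohort
    alt = bundle.measurements.copy()
    conv = {
        "hemoglobin": ("g/dL", 0.1),
        "creatinine": ("mg/dL", 113.12 / 1e4),
        "potassium": ("mEq/L", 1.0),
    }
    for analyte, (unit, factor) in conv.items():
        mask = alt["analyte"] == analyte
        alt.loc[mask, "value"] = alt.loc[mask, "value"] * factor
        alt.loc[mask, "unit"] = unit
    alt_bundle = CohortBundle(
        admissions=bundle.admissions,
        measurements=alt,
        diagnoses=bundle.diagnoses,
        unit_stays=bundle.unit_stays,
        reference_ranges=bundle.reference_ranges,
    )
    a = label_cohort(bundle, list(DEFS.values()))
    b = label_cohort(alt_bundle, list(DEFS.values()))
    for col in ("lab_abnormal", "lab_mild", "lab_moderate", "lab_severe"):
        assert (a[col] == b[col]).all()


def test_label_cohort_is_deterministic(small_cohort):
    bundle, _ = small_cohort
    pdt.assert_frame_equal(
        label_cohort(bundle, list(DEFS.values())),
        label_cohort(bundle, list(DEFS.values())),
    )


def test_missing_reference_range_names_the_triple(small_cohort):
    bundle, _ = small_cohort
    ranges = bundle.reference_ranges
    pruned = ranges.loc[~((ranges["analyte"] == "sodium") & (ranges["institution"] == "site_b"))]
    broken = CohortBundle(
        admissions=bundle.admissions,
        measurements=bundle.measurements,
        diagnoses=bundle.diagnoses,
        unit_stays=bundle.unit_stays,
        reference_ranges=pruned.reset_index(drop=True),
    )
    with pytest.raises(LabelingError, match="site_b.*sodium|sodium.*site_b"):
        label_cohort(broken, [DEFS["hyponatremia"]])
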