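import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from labconcord.concordance import (
    TwoByTwoTable,
    UndefinedMetricError,
    cohen_kappa,
    metric_table,
    prevalence_table,
    round_pct,
    sensitivity,
    specificity,
    spearman_rho,
    summarize_metrics,
    two_by_two,
    unit_weighted_proportions,
)


def brute_force_kappa(t: TwoByTwoTable) -> float:
    """Independent oracle: expand the table into label vectors, measure
    observed agreement by direct comparison and chance agreement by
    enumerating every cross pair of the two raters' assignments."""
    diag = np.array([1] * t.tp + [1] * t.fp + [0] * t.fn + [0] * t.tn)
    lab = np.array([1] * t.tp + [0] * t.fp + [1] * t.fn + [0] * t.tn)
    po = float((diag == lab).mean())
    pe = float((diag[:, None] == lab[None, :]).mean())
    if pe == 1.0:
        raise UndefinedMetricError("degenerate")
    return (po - pe) / (1.0 - pe)


def _label_frame(pairs):
    return pd.DataFrame(
        {
            "admission_id": [f"a{i}" for i in range(len(pairs))],
            "outcome": "aki",
            "lab_abnormal": [l for _, l in pairs],
            "lab_mild": [l for _, l in pairs],
            "lab_moderate": False,
            "lab_severe": False,
            "diagnosis_positive": [d for d, _ in pairs],
        }
    )


def test_two_by_two_direct_tally():
    labels = _label_frame([(True, True), (False, True), (False, False), (True, False)])
    t = two_by_two(labels, "aki", "abnormal")
    assert (t.tp, t.fn, t.tn, t.fp) == (1, 1, 1, 1)
    assert t.n == 4


def test_two_by_two_all_negative():
    labels = _label_frame([(False, False)] * 5)
    t = two_by_two(labels, "aki", "mild")
    assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 0, 5)


def test_two_by_two_empty_raises():
    with pytest.raises(ValueError, match="no label rows"):
        two_by_two(_label_frame([]), "aki", "mild")


@pytest.mark.parametrize(
    "table, expected",
    [
        (TwoByTwoTable(50, 0, 0, 50), 1.0),
        (TwoByTwoTable(25, 25, 25, 25), 0.0),
        (TwoByTwoTable(10, 5, 40, 945), 0.2913),  # po=0.955, pe=0.9365
    ],
)
def test_kappa_known_values(table, expected):
    assert cohen_kappa(table) == pytest.approx(expected, abs=5e-5)


def test_kappa_degenerate_margins_raise():
    with pytest.raises(UndefinedMetricError, match="kappa"):
        cohen_kappa(TwoByTwoTable(5, 0, 0, 0))


def test_kappa_matches_brute_force_small_tables():
    """Closed form equals pair-enumeration agreement for all tables n <= 12."""
    n_max = 12
    for tp in range(n_max + 1):
        for fp in range(n_max + 1 - tp):
            for fn in range(n_max + 1 - tp - fp):
                for tn in range(n_max + 1 - tp - fp - fn):
                    t = TwoByTwoTable(tp, fp, fn, tn)
                    if t.n == 0:
                        continue
                    try:
                        expected = brute_force_kappa(t)
                    except UndefinedMetricError:
                        with pytest.raises(UndefinedMetricError):
                            cohen_kappa(t)
                        continue
                    assert cohen_kappa(t) == pytest.approx(expected, abs=1e-12)


def test_kappa_one_iff_no_disagreement_and_rater_symmetry():
    assert cohen_kappa(TwoByTwoTable(3, 0, 0, 7)) == 1.0
    t = TwoByTwoTable(8, 3, 5, 20)
    swapped = TwoByTwoTable(t.tp, t.fn, t.fp, t.tn)  # swap the two raters
    assert cohen_kappa(t) == pytest.approx(cohen_kappa(swapped), abs=1e-12)
    assert cohen_kappa(t) < 1.0


def test_sensitivity_specificity_values_and_errors():
    assert sensitivity(TwoByTwoTable(10, 0, 40, 0)) == pytest.approx(0.2)
    assert specificity(TwoByTwoTable(0, 5, 0, 945)) == pytest.approx(945 / 950)
    with pytest.raises(UndefinedMetricError):
        sensitivity(TwoByTwoTable(0, 3, 0, 7))
    with pytest.raises(UndefinedMetricError):
        specificity(TwoByTwoTable(3, 0, 7, 0))


@settings(max_examples=50, derandomize=True)
@given(
    tp=st.integers(0, 20),
    fp=st.integers(0, 20),
    fn=st.integers(0, 20),
    tn=st.integers(0, 20),
    k=st.integers(2, 7),
)
def test_sens_spec_invariant_to_cell_scaling(tp, fp, fn, tn, k):
    t = TwoByTwoTable(tp, fp, fn, tn)
    ts = TwoByTwoTable(tp * k, fp * k, fn * k, tn * k)
    if tp + fn > 0:
        assert sensitivity(t) == pytest.approx(sensitivity(ts))
    if fp + tn > 0:
        assert specificity(t) == pytest.approx(specificity(ts))


@pytest.mark.parametrize(
    "count, denom, expected",
    [
        (4553, 59298, 7.7),
        (38, 59298, 0.1),
        (2132, 24639, 8.7),
        (297, 59298, 0.5),
        (0, 100, 0.0),
        (25, 1000, 2.5),  # exact half rounds away from zero
    ],
)
def test_percentage_rendering(count, denom, expected):
    assert round_pct(count, denom) == expected


def test_prevalence_table_counts_and_denominators():
    labels = _label_frame([(True, True), (False, True), (False, False)])
    cohorts = pd.Series("c1", index=labels["admission_id"])
    prev = prevalence_table(labels, cohorts)
    row = prev.loc[(prev["label_type"] == "mild")].iloc[0]
    assert (row["count"], row["denominator"], row["pct"]) == (2, 3, 66.7)
    assert len(prev) == 5  # five label types x one outcome x one cohort


def test_summarize_metrics_hand_values():
    metrics = pd.DataFrame(
        {
            "cohort": "c1",
            "severity": "mild",
            "outcome": list("abcdefg"),
            "kappa": [0.1, 0.2, 0.25, 0.3, 0.5, 0.55, 0.9],
            "sensitivity": [0.2, 0.4, 0.6, np.nan, 0.5, 0.3, 0.1],
            "specificity": 0.9,
        }
    )
    out = summarize_metrics(metrics)
    k = out.loc[out["metric"] == "kappa"].iloc[0]
    assert k["mean"] == pytest.approx(2.8 / 7)
    assert k["median"] == pytest.approx(0.3)
    assert (k["min"], k["max"]) == (0.1, 0.9)
    s = out.loc[out["metric"] == "sensitivity"].iloc[0]
    assert s["n_undefined"] == 1 and s["n_values"] == 6
    single = summarize_metrics(
        metrics.iloc[:1].assign(sensitivity=0.4, specificity=0.9)
    )
    assert (single["sd"] == 0).all() and single["degenerate"].all()


def test_unit_weighted_proportions_hand_fixture():
    # adm1 visits u1+u2 (weight 1/2 each), positive
    # adm2 visits u1 (weight 1), negative; adm3 visits u3, positive
    labels = _label_frame([(True, True), (False, False), (True, True)])
    stays = pd.DataFrame(
        {
            "admission_id": ["a0", "a0", "a1", "a2"],
            "unit_id": ["u1", "u2", "u1", "u3"],
        }
    )
    out = unit_weighted_proportions(labels, stays, "aki").set_index("unit_id")
    assert out.loc["u2", "prop_mild"] == pytest.approx(1.0)
    assert out.loc["u1", "prop_mild"] == pytest.approx(0.5 / 1.5)
    assert out.loc["u3", "prop_mild"] == pytest.approx(1.0)
    # conservation: total weight across units equals number of admissions
    assert out["total_weight"].sum() == pytest.approx(3.0)
    # lab proportion is the average across the four severity levels
    assert out.loc["u1", "lab_proportion"] == pytest.approx(
        (out.loc["u1", "prop_abnormal"] + out.loc["u1", "prop_mild"]) / 4
    )


def test_unit_weight_conservation_on_simulated_cohort(small_cohort):
    from labconcord.labeling import default_outcome_definitions, label_cohort

    bundle, _ = small_cohort
    labels = label_cohort(bundle, default_outcome_definitions())
    out = unit_weighted_proportions(labels, bundle.unit_stays, "anemia")
    n_with_stays = bundle.unit_stays["admission_id"].nunique()
    assert out["total_weight"].sum() == pytest.approx(n_with_stays)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 2, 3, 4), (10, 20, 30, 40), 1.0),
        ((1, 2, 3, 4), (8, 6, 4, 2), -1.0),
        ((1, 2, 3, 4), (2, 1, 4, 3), 0.6),  # 1 - 6*4/(4*15)
    ],
)
def test_spearman_known_values(x, y, expected):
    assert spearman_rho(x, y) == pytest.approx(expected)


def test_spearman_constant_vector_undefined():
    with pytest.raises(UndefinedMetricError):
        spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@settings(max_examples=40, derandomize=True)
@given(st.lists(st.integers(-200, 200), min_size=4, max_size=12, unique=True))
def test_spearman_invariant_under_monotone_transform(xs):
    xs = np.array(xs, dtype=float)
    rng = np.random.default_rng(0)
    ys = rng.permutation(len(xs)).astype(float)
    base = spearman_rho(xs, ys)
    assert spearman_rho(np.exp(xs / 100.0), ys) == pytest.approx(base)
    assert spearman_rho(xs, 3.0 * ys + 7.0) == pytest.approx(base)
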