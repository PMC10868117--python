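"""Agreement of diagnosis-based labels against lab-based gold standards.

Treating the diagnosis-based label as the test and each lab-based label
(abnormal, mild, moderate, severe) as the gold standard, this module
computes 2x2 contingency tables, Cohen's kappa, sensitivity and
specificity; prevalence tables; distributional summaries of the metrics
across outcomes; and per-hospital-unit weighted label proportions with
their Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SEVERITY_LEVELS",
    "LABEL_TYPES",
    "UndefinedMetricError",
    "TwoByTwoTable",
    "two_by_two",
    "cohen_kappa",
    "sensitivity",
    "specificity",
    "round_pct",
    "prevalence_table",
    "metric_table",
    "summarize_metrics",
    "unit_weighted_proportions",
    "spearman_rho",
]

#: Lab gold-standard levels a diagnosis label is evaluated against.
SEVERITY_LEVELS = ("abnormal", "mild", "moderate", "severe")

#: The five per-admission label types.
LABEL_TYPES = SEVERITY_LEVELS + ("diagnosis",)

_LABEL_COLUMNS = {
    "abnormal": "lab_abnormal",
    "mild": "lab_mild",
    "moderate": "lab_moderate",
    "severe": "lab_severe",
    "diagnosis": "diagnosis_positive",
}


class UndefinedMetricError(ValueError):
    """A metric's defining ratio has a zero denominator (or kappa's chance
    agreement equals 1)."""


@dataclass(frozen=True)
class TwoByTwoTable:
    """Diagnosis label (test) vs lab label (gold standard) counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def two_by_two(labels: pd.DataFrame, outcome: str, severity: str) -> TwoByTwoTable:
    """Tally the 2x2 table for one outcome at one lab severity level."""
    if severity not in SEVERITY_LEVELS:
        raise ValueError(f"severity must be one of {SEVERITY_LEVELS}, got {severity!r}")
    sub = labels.loc[labels["outcome"] == outcome]
    if sub.empty:
        raise ValueError(f"no label rows for outcome {outcome!r}")
    gold = sub[_LABEL_COLUMNS[severity]].to_numpy(dtype=bool)
    test = sub["diagnosis_positive"].to_numpy(dtype=bool)
    return TwoByTwoTable(
        tp=int((test & gold).sum()),
        fp=int((test & ~gold).sum()),
        fn=int((~test & gold).sum()),
        tn=int((~test & ~gold).sum()),
    )


def cohen_kappa(t: TwoByTwoTable) -> float:
    """Chance-corrected agreement kappa = (po - pe) / (1 - pe).

    po is the observed agreement (tp + tn) / n; pe the agreement expected
    from the two raters' margins.  Undefined when a margin is degenerate
    (pe = 1).
    """
    n = t.n
    if n == 0:
        raise UndefinedMetricError("empty table")
    po = (t.tp + t.tn) / n
    pe = ((t.tp + t.fn) * (t.tp + t.fp) + (t.fp + t.tn) * (t.fn + t.tn)) / (n * n)
    if pe == 1.0:
        raise UndefinedMetricError("kappa undefined: degenerate margins (pe = 1)")
    return (po - pe) / (1.0 - pe)


def sensitivity(t: TwoByTwoTable) -> float:
    """tp / (tp + fn) of the diagnosis label against the lab gold standard."""
    if t.tp + t.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no gold-positive admissions")
    return t.tp / (t.tp + t.fn)


def specificity(t: TwoByTwoTable) -> float:
    """tn / (fp + tn) of the diagnosis label against the lab gold standard."""
    if t.fp + t.tn == 0:
        raise UndefinedMetricError("specificity undefined: no gold-negative admissions")
    return t.tn / (t.fp + t.tn)


def round_pct(count: int, denominator: int, digits: int = 1) -> float:
    """Percentage rounded half-away-from-zero (display convention)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * count) / Decimal(denominator)
    q = Decimal(1).scaleb(-digits)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def prevalence_table(labels: pd.DataFrame, cohorts: pd.Series) -> pd.DataFrame:
    """Counts and percentages of positive labels per cohort x label type x
    outcome.

    ``cohorts`` maps admission_id to a cohort name.  The denominator for
    every cell is the cohort's full admission count; percentages are
    rendered to one decimal.
    """
    df = labels.copy()
    df["cohort"] = df["admission_id"].map(cohorts)
    if df["cohort"].isna().any():
        raise ValueError("every labeled admission needs a cohort assignment")
    denominators = (
        df.loc[df["outcome"] == df["outcome"].iloc[0]].groupby("cohort")["admission_id"].nunique()
    )
    rows = []
    for label_type, col in _LABEL_COLUMNS.items():
        counts = df.groupby(["cohort", "outcome"], observed=True)[col].sum()
        for (cohort, outcome), count in counts.items():
            denom = int(denominators[cohort])
            rows.append(
                {
                    "cohort": cohort,
                    "label_type": label_type,
                    "outcome": outcome,
                    "count": int(count),
                    "denominator": denom,
                    "pct": round_pct(int(count), denom),
                }
            )
    return pd.DataFrame(rows)


def metric_table(labels: pd.DataFrame, cohorts: pd.Series) -> pd.DataFrame:
    """Kappa / sensitivity / specificity per cohort x severity x outcome.

    Metrics whose denominators are degenerate are reported as NaN with
    ``defined = False`` (they are excluded from summaries, not imputed).
    """
    df = labels.copy()
    df["cohort"] = df["admission_id"].map(cohorts)
    rows = []
    for cohort, sub in df.groupby("cohort"):
        for outcome in sub["outcome"].unique():
            for severity in SEVERITY_LEVELS:
                t = two_by_two(sub, outcome, severity)
                row = {"cohort": cohort, "severity": severity, "outcome": outcome}
                for name, fn in (
                    ("kappa", cohen_kappa),
                    ("sensitivity", sensitivity),
                    ("specificity", specificity),
                ):
                    try:
                        row[name] = fn(t)
                    except UndefinedMetricError:
                        row[name] = float("nan")
                rows.append(row)
    out = pd.DataFrame(rows)
    out["defined"] = ~out[["kappa", "sensitivity", "specificity"]].isna().any(axis=1)
    return out


def summarize_metrics(metrics: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Distributional summary of per-outcome metric values.

    One row per group x metric with mean, sd, median, iqr, min, max and
    the number of undefined (excluded) values.  A single-value group gets
    sd = 0 and ``degenerate = True``.
    """
    by = by or ["cohort", "severity"]
    rows = []
    for keys, sub in metrics.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for metric in ("kappa", "sensitivity", "specificity"):
            vals = sub[metric].dropna().to_numpy()
            if vals.size == 0:
                raise UndefinedMetricError(
                    f"no defined {metric} values in group {dict(zip(by, keys))}"
                )
            q25, q75 = np.percentile(vals, [25, 75])
            rows.append(
                {
                    **dict(zip(by, keys)),
                    "metric": metric,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "median": float(np.median(vals)),
                    "iqr": float(q75 - q25),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n_values": int(vals.size),
                    "n_undefined": int(sub[metric].isna().sum()),
                    "degenerate": vals.size == 1,
                }
            )
    return pd.DataFrame(rows)


def unit_weighted_proportions(
    labels: pd.DataFrame, unit_stays: pd.DataFrame, outcome: str
) -> pd.DataFrame:
    """Weighted positive-label proportions per hospital unit.

    Each admission contributes weight 1/k to each of its k distinct
    visited units, so its total contribution across units is 1.  Per unit,
    a label's proportion is the weighted fraction of positive admissions;
    the lab proportion is computed at each severity level and then
    averaged across the four levels.  Admissions without any unit stay are
    ignored (they carry no unit information).
    """
    sub = labels.loc[labels["outcome"] == outcome]
    stays = unit_stays.drop_duplicates(subset=["admission_id", "unit_id"]).copy()
    k = stays.groupby("admission_id")["unit_id"].transform("count")
    stays["weight"] = 1.0 / k
    merged = stays.merge(sub, on="admission_id", how="inner")
    if merged.empty:
        raise ValueError(f"no unit stays matching labeled admissions for {outcome!r}")

    total = merged.groupby("unit_id")["weight"].sum()
    out = pd.DataFrame({"unit_id": total.index, "total_weight": total.to_numpy()})
    for level, col in _LABEL_COLUMNS.items():
        pos = merged.loc[merged[col], :].groupby("unit_id")["weight"].sum()
        out[f"prop_{level}"] = (
            out["unit_id"].map(pos).fillna(0.0).to_numpy() / out["total_weight"].to_numpy()
        )
    out["lab_proportion"] = out[[f"prop_{s}" for s in SEVERITY_LEVELS]].mean(axis=1)
    out["diagnosis_proportion"] = out["prop_diagnosis"]
    return out.reset_index(drop=True)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_rho needs two equal-length vectors of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedMetricError("spearman rho undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
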