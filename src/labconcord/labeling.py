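"""Lab-based and diagnosis-based outcome labels per admission.

For each of seven lab-defined clinical outcomes (acute kidney injury,
hyperkalemia, hypoglycemia, hyponatremia, anemia, neutropenia and
thrombocytopenia) an admission receives five binary labels:

* ``lab_abnormal`` — the admission's extreme lab value falls outside the
  institution- and age-group-specific reference range, on the outcome's
  side only (above OR below, never both);
* ``lab_mild`` / ``lab_moderate`` / ``lab_severe`` — the extreme value
  crosses fixed severity cutoffs.  Severity is nested: a severe admission
  is also mild and moderate;
* ``diagnosis_positive`` — at least one diagnosis code on the admission
  matches the outcome's code set.

All cutoffs, reference ranges and code sets are configuration, loaded by
default from the package's editable ``defaults/`` files.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import ANALYTES, CohortBundle, assign_age_groups

__all__ = [
    "CANONICAL_UNITS",
    "LabelingError",
    "UnitError",
    "SeverityThresholds",
    "CodeSetEntry",
    "CodeSet",
    "OutcomeDefinition",
    "normalize_unit",
    "normalize_measurements",
    "admission_extremum",
    "severity_labels",
    "abnormal_label",
    "diagnosis_label",
    "label_cohort",
    "default_outcome_definitions",
    "load_outcome_definitions",
    "default_reference_ranges",
]


class LabelingError(ValueError):
    """Raised when labeling preconditions are violated."""


class UnitError(LabelingError):
    """Raised for a unit not recognized for an analyte."""


#: Canonical reporting unit per analyte.
CANONICAL_UNITS = {
    "creatinine": "umol/L",
    "potassium": "mmol/L",
    "glucose": "mmol/L",
    "sodium": "mmol/L",
    "anc": "10^9/L",
    "hemoglobin": "g/L",
    "platelets": "10^9/L",
}

# Multiplicative factors from a recognized unit dialect to the canonical
# unit.  Creatinine mg/dL -> umol/L uses the molar mass 113.12 g/mol;
# glucose mg/dL -> mmol/L uses 180.156 g/mol.
_UNIT_FACTORS: dict[str, dict[str, float]] = {
    "creatinine": {"umol/l": 1.0, "µmol/l": 1.0, "mg/dl": 1e4 / 113.12},
    "potassium": {"mmol/l": 1.0, "meq/l": 1.0},
    "sodium": {"mmol/l": 1.0, "meq/l": 1.0},
    "glucose": {"mmol/l": 1.0, "mg/dl": 10.0 / 180.156},
    "anc": {"10^9/l": 1.0, "x10^9/l": 1.0, "10^3/ul": 1.0, "cells/ul": 1e-3},
    "hemoglobin": {"g/l": 1.0, "g/dl": 10.0},
    "platelets": {"10^9/l": 1.0, "x10^9/l": 1.0, "10^3/ul": 1.0, "cells/ul": 1e-3},
}


@dataclass(frozen=True)
class SeverityThresholds:
    """Nested severity cutoffs in the analyte's canonical unit.

    ``kind="absolute"`` cutoffs are compared to the extreme value directly;
    ``kind="ref_high_multiple"`` cutoffs are multiples of the admission's
    upper reference bound (used for hypercreatinemia, where what counts as
    a high creatinine depends strongly on age).
    """

    mild: float
    moderate: float
    severe: float
    kind: str = "absolute"

    def validate(self, direction: str) -> None:
        order = (self.mild, self.moderate, self.severe)
        if direction == "below" and not (order[0] >= order[1] >= order[2]):
            raise LabelingError(f"below-direction cutoffs must be non-increasing: {order}")
        if direction == "above" and not (order[0] <= order[1] <= order[2]):
            raise LabelingError(f"above-direction cutoffs must be non-decreasing: {order}")


@dataclass(frozen=True)
class CodeSetEntry:
    vocabulary: str
    code: str
    mode: str = "prefix"  # "exact" or "prefix"


@dataclass(frozen=True)
class CodeSet:
    outcome: str
    entries: tuple[CodeSetEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise LabelingError(f"code set for {self.outcome!r} is empty")


@dataclass(frozen=True)
class OutcomeDefinition:
    """Everything needed to label one outcome.

    ``extremum`` is ``max`` iff ``direction`` is ``above``: outcomes defined
    by high values (hypercreatinemia, hyperkalemia) use the admission's
    maximum, all others the minimum.
    """

    outcome: str
    analyte: str
    direction: str  # "above" | "below"
    thresholds: SeverityThresholds
    code_set: CodeSet
    default_code: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise LabelingError(f"unknown direction {self.direction!r}")
        if self.analyte not in ANALYTES:
            raise LabelingError(f"unknown analyte {self.analyte!r}")
        self.thresholds.validate(self.direction)

    @property
    def extremum(self) -> str:
        return "max" if self.direction == "above" else "min"


# --------------------------------------------------------------------------
# Unit normalization
# --------------------------------------------------------------------------

def unit_factor(unit: str, analyte: str) -> float:
    try:
        table = _UNIT_FACTORS[analyte]
    except KeyError:
        raise UnitError(f"unknown analyte {analyte!r}") from None
    try:
        return table[unit.strip().lower()]
    except KeyError:
        raise UnitError(f"unrecognized unit {unit!r} for analyte {analyte!r}") from None


def normalize_unit(value: float, unit: str, analyte: str) -> float:
    """Convert a lab value to the analyte's canonical unit."""
    return value * unit_factor(unit, analyte)


def normalize_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """Vectorized unit normalization of a measurements table."""
    out = measurements.copy()
    factors = np.ones(len(out))
    for analyte, table in _UNIT_FACTORS.items():
        mask = (out["analyte"] == analyte).to_numpy()
        if not mask.any():
            continue
        units = out.loc[mask, "unit"].astype(str).str.strip().str.lower()
        unknown = ~units.isin(table)
        if unknown.any():
            bad = units[unknown].iloc[0]
            raise UnitError(f"unrecognized unit {bad!r} for analyte {analyte!r}")
        factors[mask] = units.map(table).to_numpy()
    out["value"] = out["value"].to_numpy(dtype=float) * factors
    out["unit"] = out["analyte"].map(CANONICAL_UNITS)
    return out


# --------------------------------------------------------------------------
# Per-admission label primitives
# --------------------------------------------------------------------------

def admission_extremum(measurements: pd.DataFrame, definition: OutcomeDefinition) -> float:
    """Extreme (max or min per the outcome's direction) normalized value of
    the outcome's analyte, or NaN when the analyte was never measured."""
    values = measurements.loc[measurements["analyte"] == definition.analyte, "value"]
    if values.empty:
        return float("nan")
    return float(values.max() if definition.extremum == "max" else values.min())


def severity_labels(
    extremum: float, thresholds: SeverityThresholds, direction: str
) -> tuple[bool, bool, bool]:
    """(mild, moderate, severe) flags for one extreme value.

    Strict inequality at the cutoff; a missing extremum is all-False.
    Nesting (severe => moderate => mild) follows from the cutoff ordering.
    """
    if thresholds.kind != "absolute":
        raise LabelingError("relative thresholds must be resolved before severity_labels")
    if extremum is None or np.isnan(extremum):
        return (False, False, False)
    if direction == "below":
        return (
            extremum < thresholds.mild,
            extremum < thresholds.moderate,
            extremum < thresholds.severe,
        )
    return (
        extremum > thresholds.mild,
        extremum > thresholds.moderate,
        extremum > thresholds.severe,
    )


def abnormal_label(extremum: float, low: float, high: float, direction: str) -> bool:
    """Outside-reference-range flag, on the outcome's side only."""
    if extremum is None or np.isnan(extremum):
        return False
    return extremum < low if direction == "below" else extremum > high


def diagnosis_label(records: pd.DataFrame, code_set: CodeSet) -> bool:
    """True iff at least one diagnosis record matches the code set."""
    if records.empty:
        return False
    codes = records["code"].astype(str)
    for entry in code_set.entries:
        if entry.mode == "exact":
            if (codes == entry.code).any():
                return True
        else:
            if codes.str.startswith(entry.code).any():
                return True
    return False


# --------------------------------------------------------------------------
# Cohort labeling
# --------------------------------------------------------------------------

def _resolve_cutoffs(
    defn: OutcomeDefinition, admissions: pd.DataFrame, ranges: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-admission (low, high, mild, moderate, severe) cutoff frame.

    Relative (``ref_high_multiple``) thresholds become multiples of each
    admission's upper reference bound.  Raises if any admission lacks a
    matching reference-range row.
    """
    sub = ranges.loc[ranges["analyte"] == defn.analyte, ["institution", "age_group", "low", "high"]]
    merged = admissions.merge(sub, on=["institution", "age_group"], how="left")
    if merged["low"].isna().any():
        row = merged.loc[merged["low"].isna()].iloc[0]
        raise LabelingError(
            "no reference range for "
            f"(institution={row['institution']!r}, analyte={defn.analyte!r}, "
            f"age_group={row['age_group']!r})"
        )
    t = defn.thresholds
    if t.kind == "ref_high_multiple":
        base = merged["high"].to_numpy(dtype=float)
        cuts = np.column_stack([base * t.mild, base * t.moderate, base * t.severe])
    else:
        cuts = np.tile([t.mild, t.moderate, t.severe], (len(merged), 1))
    return merged, cuts


def _diagnosis_positive_ids(diagnoses: pd.DataFrame, code_set: CodeSet) -> set:
    codes = diagnoses["code"].astype(str)
    mask = pd.Series(False, index=diagnoses.index)
    for entry in code_set.entries:
        if entry.mode == "exact":
            mask |= codes == entry.code
        else:
            mask |= codes.str.startswith(entry.code)
    return set(diagnoses.loc[mask, "admission_id"])


def label_cohort(
    bundle: CohortBundle,
    definitions: list[OutcomeDefinition],
    age_groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Label every admission for every outcome definition.

    Returns a tidy frame with exactly ``n_admissions * len(definitions)``
    rows and columns ``admission_id, outcome, lab_abnormal, lab_mild,
    lab_moderate, lab_severe, diagnosis_positive, extremum_value``.
    Admissions with no measurement of an analyte are labeled negative for
    that outcome's lab labels (they remain in every denominator).

    ``age_groups`` (aligned with ``bundle.admissions``) may be supplied for
    cohorts whose reference ranges are not stratified by pediatric group;
    by default pediatric groups are derived from ``age_at_admission``.
    """
    adm = bundle.admissions[["admission_id", "institution"]].copy()
    if age_groups is None:
        adm["age_group"] = assign_age_groups(bundle.admissions["age_at_admission"]).astype(str)
    else:
        adm["age_group"] = age_groups.astype(str).to_numpy()

    norm = normalize_measurements(bundle.measurements)
    blocks: list[pd.DataFrame] = []
    for defn in definitions:
        merged, cuts = _resolve_cutoffs(defn, adm, bundle.reference_ranges)
        sub = norm.loc[norm["analyte"] == defn.analyte, ["admission_id", "value"]]
        grouped = sub.groupby("admission_id")["value"]
        ext = (grouped.max() if defn.extremum == "max" else grouped.min())
        x = merged["admission_id"].map(ext).to_numpy(dtype=float)

        present = ~np.isnan(x)
        if defn.direction == "below":
            mild = present & (x < cuts[:, 0])
            moderate = present & (x < cuts[:, 1])
            severe = present & (x < cuts[:, 2])
            abnormal = present & (x < merged["low"].to_numpy(dtype=float))
        else:
            mild = present & (x > cuts[:, 0])
            moderate = present & (x > cuts[:, 1])
            severe = present & (x > cuts[:, 2])
            abnormal = present & (x > merged["high"].to_numpy(dtype=float))

        positive_ids = _diagnosis_positive_ids(bundle.diagnoses, defn.code_set)
        diag = merged["admission_id"].isin(positive_ids).to_numpy()

        blocks.append(
            pd.DataFrame(
                {
                    "admission_id": merged["admission_id"],
                    "outcome": defn.outcome,
                    "lab_abnormal": abnormal,
                    "lab_mild": mild,
                    "lab_moderate": moderate,
                    "lab_severe": severe,
                    "diagnosis_positive": diag,
                    "extremum_value": x,
                }
            )
        )
    out = pd.concat(blocks, ignore_index=True)
    # nesting is structural (cutoff ordering) but cheap to assert
    assert not (out["lab_severe"] & ~out["lab_moderate"]).any()
    assert not (out["lab_moderate"] & ~out["lab_mild"]).any()
    return out


# --------------------------------------------------------------------------
# Default configuration
# --------------------------------------------------------------------------

def _defaults_path(name: str):
    return resources.files("labconcord").joinpath("defaults", name)


def load_outcome_definitions(
    thresholds_path: str | Path, code_sets_path: str | Path
) -> list[OutcomeDefinition]:
    """Build outcome definitions from threshold and code-set config files."""
    with open(thresholds_path) as fh:
        tcfg = yaml.safe_load(fh)
    with open(code_sets_path) as fh:
        ccfg = yaml.safe_load(fh)
    definitions = []
    for outcome, spec in tcfg["outcomes"].items():
        entries = tuple(
            CodeSetEntry(e["vocabulary"], str(e["code"]), e.get("mode", "prefix"))
            for e in ccfg[outcome]
        )
        definitions.append(
            OutcomeDefinition(
                outcome=outcome,
                analyte=spec["analyte"],
                direction=spec["direction"],
                thresholds=SeverityThresholds(
                    float(spec["mild"]),
                    float(spec["moderate"]),
                    float(spec["severe"]),
                    kind=spec.get("kind", "absolute"),
                ),
                code_set=CodeSet(outcome=outcome, entries=entries),
                default_code=str(spec.get("default_code", "")),
            )
        )
    return definitions


def default_outcome_definitions() -> list[OutcomeDefinition]:
    """The seven shipped outcome definitions."""
    with resources.as_file(_defaults_path("thresholds.yaml")) as tp, resources.as_file(
        _defaults_path("code_sets.yaml")
    ) as cp:
        return load_outcome_definitions(tp, cp)


def default_reference_ranges() -> pd.DataFrame:
    """Shipped two-institution synthetic reference-range table."""
    with resources.as_file(_defaults_path("reference_ranges.csv")) as path:
        return pd.read_csv(path)
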