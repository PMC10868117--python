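"""Canonical in-memory tables for multi-institution inpatient cohorts.

The analysis operates on five tables extracted from an EHR warehouse:
admissions (one row per inpatient stay), lab measurements, diagnosis
records, hospital-unit stays, and institution/age-group-specific lab
reference ranges.  This module reads the two supported delimited-text
dialects ("flat" simple column names, "omop" mirroring OMOP-CDM style
visit/measurement/condition_occurrence naming), validates them into a
:class:`CohortBundle`, applies cohort eligibility rules, and assigns
NICHD pediatric age groups.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "AGE_GROUPS",
    "YEAR_DAYS",
    "PEDIATRIC_MIN_DAYS",
    "BundleError",
    "CohortConfig",
    "CohortBundle",
    "read_bundle",
    "write_bundle",
    "filter_eligible",
    "assign_age_group",
    "assign_age_groups",
]

#: Recognized lab analytes, in the order they are conventionally reported.
ANALYTES = (
    "creatinine",
    "potassium",
    "glucose",
    "sodium",
    "anc",
    "hemoglobin",
    "platelets",
)

#: NICHD pediatric age groups used as model strata.
AGE_GROUPS = (
    "infant",
    "toddler",
    "early_childhood",
    "middle_childhood",
    "early_adolescence",
)

SEXES = ("female", "male", "unknown")

#: Days per year used to convert the year-denominated group boundaries to
#: the day resolution of ``age_at_admission``.  Configurable because no
#: birthdates exist in the schema with which to do calendar arithmetic.
YEAR_DAYS = 365.25

#: Neonates aged 1-27 days are excluded from pediatric cohorts.
PEDIATRIC_MIN_DAYS = 28

# Age-group lower bounds in days (upper bound of the last group is the
# pediatric limit, 18 years).  Infant starts at 28 days; toddler at 366
# days (just past 12 months); the remaining groups at 3, 6 and 12 years.
_GROUP_LOWER_DAYS = (
    PEDIATRIC_MIN_DAYS,
    366,
    3 * YEAR_DAYS,
    6 * YEAR_DAYS,
    12 * YEAR_DAYS,
)
_PEDIATRIC_MAX_DAYS = 18 * YEAR_DAYS  # exclusive


class BundleError(ValueError):
    """Fatal problem while reading or validating a cohort bundle."""


# --------------------------------------------------------------------------
# Table schemas and dialect column maps
# --------------------------------------------------------------------------

_TABLES = ("admissions", "measurements", "diagnoses", "unit_stays", "reference_ranges")

_FLAT_COLUMNS = {
    "admissions": [
        "admission_id",
        "patient_id",
        "institution",
        "admit_date",
        "discharge_date",
        "age_at_admission",
        "sex",
        "died_in_hospital",
    ],
    "measurements": ["admission_id", "analyte", "value", "unit", "collected_at"],
    "diagnoses": ["admission_id", "code", "vocabulary"],
    "unit_stays": ["admission_id", "unit_id"],
    "reference_ranges": ["institution", "analyte", "age_group", "low", "high", "unit"],
}

# Mapping dialect -> table -> {source column: canonical column}.  The OMOP
# dialect mirrors visit_occurrence / measurement / condition_occurrence /
# visit_detail naming.  Maps are plain data so callers can supply their own.
DIALECTS: dict[str, dict[str, dict[str, str]]] = {
    "flat": {t: {c: c for c in cols} for t, cols in _FLAT_COLUMNS.items()},
    "omop": {
        "admissions": {
            "visit_occurrence_id": "admission_id",
            "person_id": "patient_id",
            "care_site_source_value": "institution",
            "visit_start_date": "admit_date",
            "visit_end_date": "discharge_date",
            "age_in_days_at_visit": "age_at_admission",
            "gender_source_value": "sex",
            "death_during_visit": "died_in_hospital",
        },
        "measurements": {
            "visit_occurrence_id": "admission_id",
            "measurement_source_value": "analyte",
            "value_as_number": "value",
            "unit_source_value": "unit",
            "measurement_datetime": "collected_at",
        },
        "diagnoses": {
            "visit_occurrence_id": "admission_id",
            "condition_source_value": "code",
            "condition_source_vocabulary": "vocabulary",
        },
        "unit_stays": {
            "visit_occurrence_id": "admission_id",
            "care_site_id": "unit_id",
        },
        # reference ranges are analyst-authored config, not an EHR extract,
        # so their columns are identical in both dialects
        "reference_ranges": {c: c for c in _FLAT_COLUMNS["reference_ranges"]},
    },
}

_TABLE_FILENAMES = {
    "flat": {t: f"{t}.csv" for t in _TABLES},
    "omop": {
        "admissions": "visit_occurrence.csv",
        "measurements": "measurement.csv",
        "diagnoses": "condition_occurrence.csv",
        "unit_stays": "visit_detail.csv",
        "reference_ranges": "reference_ranges.csv",
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort eligibility rules.

    Parameters
    ----------
    window_start, window_end
        Closed admission-date window.
    age_rule
        ``"pediatric"`` keeps 28 days <= age < 18 years; ``"adult"`` keeps
        age >= 18 years.
    institution
        Optional filter to a single institution label.
    year_days
        Days-per-year convention for the 18-year boundary.
    """

    window_start: _dt.date
    window_end: _dt.date
    age_rule: str = "pediatric"
    institution: str | None = None
    year_days: float = YEAR_DAYS

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise BundleError("cohort window start must not exceed end")
        if self.age_rule not in ("pediatric", "adult"):
            raise BundleError(f"unknown age rule {self.age_rule!r}")


@dataclass
class CohortBundle:
    """Validated cohort tables plus row-level validation diagnostics."""

    admissions: pd.DataFrame
    measurements: pd.DataFrame
    diagnoses: pd.DataFrame
    unit_stays: pd.DataFrame
    reference_ranges: pd.DataFrame
    violations: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = set(self.admissions["admission_id"])
        for name in ("measurements", "diagnoses", "unit_stays"):
            table = getattr(self, name)
            if not set(table["admission_id"]).issubset(ids):
                raise BundleError(f"{name} references admission_ids missing from admissions")
        if self.admissions["admission_id"].duplicated().any():
            raise BundleError("duplicate admission_id in admissions")

    @property
    def n_admissions(self) -> int:
        return len(self.admissions)

    def write_violation_report(self, path: str | Path) -> None:
        """Write one JSON object per rejected row (JSON lines)."""
        with open(path, "w") as fh:
            for entry in self.violations:
                fh.write(json.dumps(entry) + "\n")


# --------------------------------------------------------------------------
# Reading and validation
# --------------------------------------------------------------------------

def _coerce(frame: pd.DataFrame, table: str, violations: list[dict]) -> pd.DataFrame:
    """Coerce column types, dropping rows that fail with a diagnostic."""
    bad = pd.Series(False, index=frame.index)

    def reject(mask: pd.Series, reason: str) -> None:
        for idx in frame.index[mask & ~bad]:
            violations.append({"table": table, "row": int(idx), "reason": reason})
        bad.loc[mask] = True

    if table == "admissions":
        for col in ("admit_date", "discharge_date"):
            parsed = pd.to_datetime(frame[col], errors="coerce")
            reject(parsed.isna(), f"unparseable {col}")
            frame[col] = parsed.dt.date
        age = pd.to_numeric(frame["age_at_admission"], errors="coerce")
        reject(age.isna() | (age < 0), "invalid age_at_admission")
        frame["age_at_admission"] = age.fillna(-1).astype(int)
        sex = frame["sex"].astype(str).str.lower().str.strip()
        sex = sex.replace({"f": "female", "m": "male"})
        reject(~sex.isin(SEXES), "unrecognized sex")
        frame["sex"] = sex
        died = frame["died_in_hospital"].map(
            {True: True, False: False, "true": True, "false": False, "True": True,
             "False": False, 1: True, 0: False, "1": True, "0": False}
        )
        reject(died.isna(), "invalid died_in_hospital")
        frame["died_in_hospital"] = died.fillna(False).astype(bool)
        ok = ~bad
        inverted = ok & (
            pd.to_datetime(frame.loc[ok, "discharge_date"])
            < pd.to_datetime(frame.loc[ok, "admit_date"])
        ).reindex(frame.index, fill_value=False)
        reject(inverted, "discharge_date before admit_date")
    elif table == "measurements":
        value = pd.to_numeric(frame["value"], errors="coerce")
        reject(value.isna() | (value < 0), "invalid value")
        frame["value"] = value
        analyte = frame["analyte"].astype(str).str.lower().str.strip()
        reject(~analyte.isin(ANALYTES), "unrecognized analyte")
        frame["analyte"] = analyte
        collected = pd.to_datetime(frame["collected_at"], errors="coerce")
        reject(collected.isna(), "unparseable collected_at")
        frame["collected_at"] = collected
    elif table == "diagnoses":
        code = frame["code"].astype(str).str.strip()
        reject(code.eq("") | code.eq("nan"), "empty code")
        frame["code"] = code
        frame["vocabulary"] = frame["vocabulary"].astype(str)
    elif table == "reference_ranges":
        for col in ("low", "high"):
            v = pd.to_numeric(frame[col], errors="coerce")
            reject(v.isna(), f"invalid {col}")
            frame[col] = v
        ok = ~bad
        reject(ok & ~(frame["low"] < frame["high"]), "low not below high")

    return frame.loc[~bad].reset_index(drop=True)


def read_bundle(
    paths: dict[str, str | Path] | str | Path,
    dialect: str = "flat",
    column_maps: dict[str, dict[str, str]] | None = None,
    sep: str = ",",
) -> CohortBundle:
    """Read and validate a cohort bundle from delimited-text tables.

    ``paths`` is either a mapping of table name (``admissions`` ...
    ``reference_ranges``) to file path, or a directory containing the
    dialect's conventional file names.  Rows that fail type coercion or
    reference an unknown admission are dropped and recorded in
    ``bundle.violations``; missing files or columns are fatal.
    """
    if column_maps is None:
        if dialect not in DIALECTS:
            raise BundleError(f"unknown dialect {dialect!r}")
        column_maps = DIALECTS[dialect]
    if not isinstance(paths, dict):
        root = Path(paths)
        names = _TABLE_FILENAMES.get(dialect, _TABLE_FILENAMES["flat"])
        paths = {t: root / names[t] for t in _TABLES}

    violations: list[dict] = []
    frames: dict[str, pd.DataFrame] = {}
    for table in _TABLES:
        path = Path(paths[table])
        if not path.exists():
            raise BundleError(f"missing file for table {table!r}: {path}")
        raw = pd.read_csv(path, sep=sep, dtype=str)
        colmap = column_maps[table]
        missing = set(colmap) - set(raw.columns)
        if missing:
            raise BundleError(
                f"table {table!r} ({path.name}) lacks required columns: {sorted(missing)}"
            )
        frame = raw[list(colmap)].rename(columns=colmap)
        frames[table] = _coerce(frame, table, violations)

    ids = set(frames["admissions"]["admission_id"])
    for table in ("measurements", "diagnoses", "unit_stays"):
        frame = frames[table]
        orphan = ~frame["admission_id"].isin(ids)
        for idx in frame.index[orphan]:
            violations.append(
                {
                    "table": table,
                    "row": int(idx),
                    "reason": "orphan admission_id",
                    "admission_id": str(frame.at[idx, "admission_id"]),
                }
            )
        frames[table] = frame.loc[~orphan].reset_index(drop=True)

    frames["unit_stays"] = frames["unit_stays"].drop_duplicates(
        subset=["admission_id", "unit_id"]
    ).reset_index(drop=True)

    return CohortBundle(**frames, violations=violations)


def write_bundle(bundle: CohortBundle, outdir: str | Path, dialect: str = "flat") -> dict[str, Path]:
    """Write a bundle back to delimited text in the given dialect.

    Inverse of :func:`read_bundle` on validated bundles (round-trip safe).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    colmaps = DIALECTS[dialect]
    names = _TABLE_FILENAMES.get(dialect, _TABLE_FILENAMES["flat"])
    written: dict[str, Path] = {}
    for table in _TABLES:
        frame = getattr(bundle, table).copy()
        inverse = {canon: src for src, canon in colmaps[table].items()}
        frame = frame.rename(columns=inverse)[list(colmaps[table].keys())]
        path = outdir / names[table]
        frame.to_csv(path, index=False)
        written[table] = path
    return written


# --------------------------------------------------------------------------
# Eligibility and age groups
# --------------------------------------------------------------------------

def filter_eligible(admissions: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Apply cohort eligibility to an admissions table.

    Pediatric rule keeps ages in [28 days, 18 years); adult keeps
    >= 18 years.  The admission-date window is closed on both ends.
    Multiple admissions per patient are retained.  Idempotent.
    """
    age = admissions["age_at_admission"]
    limit = 18 * config.year_days
    if config.age_rule == "pediatric":
        keep = (age >= PEDIATRIC_MIN_DAYS) & (age < limit)
    else:
        keep = age >= limit
    admit = pd.to_datetime(admissions["admit_date"]).dt.date
    keep &= (admit >= config.window_start) & (admit <= config.window_end)
    if config.institution is not None:
        keep &= admissions["institution"] == config.institution
    return admissions.loc[keep].reset_index(drop=True)


def assign_age_group(age_at_admission: int, year_days: float = YEAR_DAYS) -> str:
    """Map an age in days to its NICHD pediatric age group.

    Groups partition [28 days, 18 years): infant [28 d, 366 d), toddler
    [366 d, 3 y), early childhood [3 y, 6 y), middle childhood [6 y, 12 y),
    early adolescence [12 y, 18 y).
    """
    if age_at_admission < PEDIATRIC_MIN_DAYS or age_at_admission >= 18 * year_days:
        raise ValueError(
            f"age {age_at_admission} days is outside the pediatric range "
            f"[{PEDIATRIC_MIN_DAYS} d, 18 y)"
        )
    bounds = (PEDIATRIC_MIN_DAYS, 366, 3 * year_days, 6 * year_days, 12 * year_days)
    idx = int(np.searchsorted(bounds, age_at_admission, side="right")) - 1
    return AGE_GROUPS[idx]


def assign_age_groups(ages: pd.Series, year_days: float = YEAR_DAYS) -> pd.Series:
    """Vectorized :func:`assign_age_group` over a Series of ages in days."""
    arr = ages.to_numpy()
    if ((arr < PEDIATRIC_MIN_DAYS) | (arr >= 18 * year_days)).any():
        bad = arr[(arr < PEDIATRIC_MIN_DAYS) | (arr >= 18 * year_days)][0]
        raise ValueError(f"age {bad} days is outside the pediatric range")
    bounds = np.array([PEDIATRIC_MIN_DAYS, 366, 3 * year_days, 6 * year_days, 12 * year_days])
    idx = np.searchsorted(bounds, arr, side="right") - 1
    return pd.Series(pd.Categorical.from_codes(idx, list(AGE_GROUPS)), index=ages.index)
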