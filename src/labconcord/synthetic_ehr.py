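"""Seeded two-institution synthetic EHR cohorts with known ground truth.

The generator emulates the statistical structure the concordance analysis
assumes, without any attempt at longitudinal physiological realism:

* multiple admissions per patient (1 + Poisson), giving the within-patient
  correlation the random-intercept models address;
* NICHD pediatric age-group mix and admission dates in a fixed window;
* per-analyte lab testing as a per-inpatient-day Bernoulli draw, with
  institution-specific probabilities (testing-frequency differences);
* a latent severity stratum per admission x outcome (none / mild band /
  moderate band / severe band); lab values are drawn uniformly between
  adjacent severity cutoffs within the band (the severe band extends one
  cutoff-width beyond the severe cutoff) and from a truncated normal
  inside the institution's reference range for non-cases, so the labeling
  rules exactly invert the latent truth;
* diagnosis codes emitted with probability
  ``expit(logit(stratum sensitivity) + patient intercept + unit shift)``
  for lab-positive strata and with a false-positive rate otherwise —
  institution- and unit-specific coding behaviour on the logit scale, so
  the association model is correctly specified under the generator
  (per-unit shifts are the deliberate misspecification toggle);
* optional per-unit "acuity" shifts on the case logit so hospital units
  differ in true lab prevalence, which is what makes unit-level
  concordance scatter informative.

Every draw derives from a single seed; the same config and seed reproduce
the bundle byte for byte.  :func:`expected_metrics` returns the analytic
prevalence / sensitivity / specificity / kappa implied by a config, the
oracle against which simulated cohorts are checked.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import special, stats

from .data_model import AGE_GROUPS, PEDIATRIC_MIN_DAYS, YEAR_DAYS, CohortBundle
from .labeling import (
    CANONICAL_UNITS,
    OutcomeDefinition,
    default_outcome_definitions,
    default_reference_ranges,
)

__all__ = [
    "STRATA",
    "ConfigError",
    "OutcomeMix",
    "InstitutionConfig",
    "SimulationConfig",
    "generate_cohort",
    "expected_metrics",
    "scenario_presets",
]

#: Latent severity strata, index-aligned with prevalence vectors.
STRATA = ("none", "mild", "moderate", "severe")

_GROUP_DAY_BOUNDS = {
    "infant": (PEDIATRIC_MIN_DAYS, 366),
    "toddler": (366, int(3 * YEAR_DAYS)),
    "early_childhood": (int(3 * YEAR_DAYS), int(6 * YEAR_DAYS)),
    "middle_childhood": (int(6 * YEAR_DAYS), int(12 * YEAR_DAYS)),
    "early_adolescence": (int(12 * YEAR_DAYS), int(18 * YEAR_DAYS)),
}


class ConfigError(ValueError):
    """Invalid simulation configuration; message carries the field path."""


@dataclass(frozen=True)
class OutcomeMix:
    """Severity mixture and coding behaviour for one outcome at one site.

    ``prevalence`` is (P(none), P(mild band), P(moderate band),
    P(severe band)); ``coding_sensitivity`` the code-emission probability
    for an average patient in each positive stratum; admissions in the
    "none" stratum are coded at ``false_positive_rate``.
    """

    prevalence: tuple[float, float, float, float]
    coding_sensitivity: tuple[float, float, float]
    false_positive_rate: float

    def validate(self, path: str) -> None:
        if len(self.prevalence) != 4 or abs(sum(self.prevalence) - 1.0) > 1e-9:
            raise ConfigError(f"{path}.prevalence must have 4 entries summing to 1")
        for name, vals in (
            ("prevalence", self.prevalence),
            ("coding_sensitivity", self.coding_sensitivity),
            ("false_positive_rate", (self.false_positive_rate,)),
        ):
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ConfigError(f"{path}.{name} must lie in [0, 1]")


@dataclass(frozen=True)
class InstitutionConfig:
    name: str
    n_patients: int
    mean_extra_admissions: float = 0.6
    age_group_probs: tuple[float, ...] = (0.151, 0.095, 0.174, 0.249, 0.331)
    mean_extra_los_days: float = 2.0
    mortality_rate: float = 0.005
    testing_prob_per_day: dict = field(default_factory=dict)
    outcomes: dict = field(default_factory=dict)  # outcome -> OutcomeMix
    n_units: int = 12
    extra_unit_prob: float = 0.3
    unit_acuity_sd: float = 0.0
    unit_coding_shift_sd: float = 0.0

    def validate(self) -> None:
        path = f"institutions[{self.name}]"
        if self.n_patients < 1:
            raise ConfigError(f"{path}.n_patients must be >= 1")
        if len(self.age_group_probs) != len(AGE_GROUPS) or abs(sum(self.age_group_probs) - 1) > 1e-9:
            raise ConfigError(f"{path}.age_group_probs must have 5 entries summing to 1")
        for analyte, q in self.testing_prob_per_day.items():
            if not 0.0 <= q <= 1.0:
                raise ConfigError(f"{path}.testing_prob_per_day[{analyte}] must be in [0, 1]")
        for outcome, mix in self.outcomes.items():
            mix.validate(f"{path}.outcomes[{outcome}]")
        if self.n_units < 1:
            raise ConfigError(f"{path}.n_units must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    institutions: tuple[InstitutionConfig, ...]
    intercept_sd: float = 1.0
    seed: int = 0
    window_start: _dt.date = _dt.date(2018, 6, 2)
    window_end: _dt.date = _dt.date(2022, 8, 1)

    def validate(self) -> None:
        if not self.institutions:
            raise ConfigError("institutions must be non-empty")
        if self.intercept_sd < 0:
            raise ConfigError("intercept_sd must be >= 0")
        for inst in self.institutions:
            inst.validate()

    def with_seed(self, seed: int) -> "SimulationConfig":
        return SimulationConfig(
            institutions=self.institutions,
            intercept_sd=self.intercept_sd,
            seed=seed,
            window_start=self.window_start,
            window_end=self.window_end,
        )

    @staticmethod
    def from_dict(raw: dict) -> "SimulationConfig":
        insts = []
        for icfg in raw["institutions"]:
            icfg = dict(icfg)
            icfg["outcomes"] = {
                name: OutcomeMix(
                    prevalence=tuple(o["prevalence"]),
                    coding_sensitivity=tuple(o["coding_sensitivity"]),
                    false_positive_rate=float(o["false_positive_rate"]),
                )
                for name, o in icfg.get("outcomes", {}).items()
            }
            icfg["age_group_probs"] = tuple(icfg.get("age_group_probs", (0.151, 0.095, 0.174, 0.249, 0.331)))
            insts.append(InstitutionConfig(**icfg))
        cfg = SimulationConfig(
            institutions=tuple(insts),
            intercept_sd=float(raw.get("intercept_sd", 1.0)),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _band_bounds(defn: OutcomeDefinition, cuts: np.ndarray, stratum: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-draw bounds per admission for positive strata.

    ``cuts`` is [n, 3] (mild, moderate, severe cutoffs).  The severe band
    extends one cutoff-width beyond the severe cutoff, floored at 0 for
    below-direction analytes.
    """
    m, mo, s = cuts[:, 0], cuts[:, 1], cuts[:, 2]
    lo = np.empty(len(stratum))
    hi = np.empty(len(stratum))
    if defn.direction == "below":
        width = mo - s
        lo_s = np.maximum(s - width, 0.0)
        lo[:] = np.select([stratum == 1, stratum == 2, stratum == 3], [mo, s, lo_s])
        hi[:] = np.select([stratum == 1, stratum == 2, stratum == 3], [m, mo, s])
    else:
        width = s - mo
        lo[:] = np.select([stratum == 1, stratum == 2, stratum == 3], [m, mo, s])
        hi[:] = np.select([stratum == 1, stratum == 2, stratum == 3], [mo, s, s + width])
    return lo, hi


def _truncnorm_in_range(rng: np.random.Generator, low: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Truncated-normal draws centred in [low, high] with sd = width / 6."""
    mean = 0.5 * (low + high)
    sd = (high - low) / 6.0
    return stats.truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, random_state=rng)


def generate_cohort(
    config: SimulationConfig,
    definitions: list[OutcomeDefinition] | None = None,
    reference_ranges: pd.DataFrame | None = None,
) -> tuple[CohortBundle, pd.DataFrame]:
    """Simulate a cohort bundle and its truth ledger.

    The ledger has one row per admission x outcome recording the latent
    severity stratum, whether the analyte was actually drawn, the emitted
    diagnosis indicator and its generating probability.
    """
    config.validate()
    definitions = definitions or default_outcome_definitions()
    ranges = reference_ranges if reference_ranges is not None else default_reference_ranges()
    rng = np.random.default_rng(config.seed)
    window_days = (config.window_end - config.window_start).days

    adm_frames, meas_frames, diag_frames, stay_frames, ledger_frames = [], [], [], [], []
    for inst in config.institutions:
        n_adm_per_patient = 1 + rng.poisson(inst.mean_extra_admissions, inst.n_patients)
        n_adm = int(n_adm_per_patient.sum())
        patient_idx = np.repeat(np.arange(inst.n_patients), n_adm_per_patient)
        patient_ids = np.array([f"{inst.name}_p{i}" for i in range(inst.n_patients)])
        admission_ids = np.array([f"{inst.name}_a{j}" for j in range(n_adm)])
        intercepts = rng.normal(0.0, config.intercept_sd, inst.n_patients)

        group_idx = rng.choice(len(AGE_GROUPS), size=inst.n_patients, p=inst.age_group_probs)
        adm_group = group_idx[patient_idx]
        lowers = np.array([_GROUP_DAY_BOUNDS[g][0] for g in AGE_GROUPS])
        uppers = np.array([_GROUP_DAY_BOUNDS[g][1] for g in AGE_GROUPS])
        ages = rng.integers(lowers[adm_group], uppers[adm_group])

        admit_offset = rng.integers(0, window_days + 1, n_adm)
        los = 1 + rng.poisson(inst.mean_extra_los_days, n_adm)
        admit = np.array([config.window_start + _dt.timedelta(days=int(d)) for d in admit_offset])
        discharge = np.array([a + _dt.timedelta(days=int(l)) for a, l in zip(admit, los)])
        sex = rng.choice(["female", "male", "unknown"], size=n_adm, p=[0.48, 0.515, 0.005])
        died = rng.random(n_adm) < inst.mortality_rate

        # hospital units: a primary unit, plus one extra with some probability
        unit_shifts = rng.normal(0.0, inst.unit_coding_shift_sd, inst.n_units) if inst.unit_coding_shift_sd > 0 else np.zeros(inst.n_units)
        unit_acuity = rng.normal(0.0, inst.unit_acuity_sd, inst.n_units) if inst.unit_acuity_sd > 0 else np.zeros(inst.n_units)
        primary_unit = rng.integers(0, inst.n_units, n_adm)
        has_extra = rng.random(n_adm) < inst.extra_unit_prob
        extra_unit = (primary_unit + 1 + rng.integers(0, max(inst.n_units - 1, 1), n_adm)) % inst.n_units
        unit_name = np.array([f"{inst.name}_u{u:02d}" for u in range(inst.n_units)])
        stay_frames.append(
            pd.DataFrame(
                {
                    "admission_id": np.concatenate([admission_ids, admission_ids[has_extra]]),
                    "unit_id": np.concatenate([unit_name[primary_unit], unit_name[extra_unit[has_extra]]]),
                }
            )
        )

        adm_frames.append(
            pd.DataFrame(
                {
                    "admission_id": admission_ids,
                    "patient_id": patient_ids[patient_idx],
                    "institution": inst.name,
                    "admit_date": admit,
                    "discharge_date": discharge,
                    "age_at_admission": ages,
                    "sex": sex,
                    "died_in_hospital": died,
                }
            )
        )

        range_lookup = {
            (row.analyte, row.age_group): (row.low, row.high)
            for row in ranges.loc[ranges["institution"] == inst.name].itertuples()
        }
        age_group_names = np.array(AGE_GROUPS)[adm_group]

        for defn in definitions:
            mix = inst.outcomes.get(defn.outcome)
            if mix is None:
                raise ConfigError(f"institutions[{inst.name}].outcomes lacks {defn.outcome!r}")
            try:
                lo_hi = np.array([range_lookup[(defn.analyte, g)] for g in age_group_names])
            except KeyError as exc:
                raise ConfigError(
                    f"reference range missing for ({inst.name}, {defn.analyte}, {exc.args[0]})"
                ) from None
            rlow, rhigh = lo_hi[:, 0], lo_hi[:, 1]

            # latent stratum, with optional per-unit acuity on the case logit
            p = np.array(mix.prevalence, dtype=float)
            if inst.unit_acuity_sd > 0 and p[0] < 1.0:
                base_logit = special.logit(np.clip(1.0 - p[0], 1e-12, 1 - 1e-12))
                p_pos = special.expit(base_logit + unit_acuity[primary_unit])
                cond = p[1:] / (1.0 - p[0])
                probs = np.column_stack([1.0 - p_pos] + [p_pos * c for c in cond])
            else:
                probs = np.tile(p, (n_adm, 1))
            u = rng.random(n_adm)
            stratum = (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)

            t = defn.thresholds
            if t.kind == "ref_high_multiple":
                cuts = np.column_stack([rhigh * t.mild, rhigh * t.moderate, rhigh * t.severe])
            else:
                cuts = np.tile([t.mild, t.moderate, t.severe], (n_adm, 1))

            q = inst.testing_prob_per_day.get(defn.analyte, 0.5)
            n_meas = rng.binomial(los, q)
            tested = n_meas > 0
            total = int(n_meas.sum())
            owner = np.repeat(np.arange(n_adm), n_meas)
            values = _truncnorm_in_range(rng, rlow[owner], rhigh[owner])
            # overwrite the first measurement of each tested case with the
            # band draw carrying the latent severity
            pos_tested = (stratum > 0) & tested
            if pos_tested.any():
                offsets = np.concatenate(([0], np.cumsum(n_meas)))[:-1]
                lo_b, hi_b = _band_bounds(defn, cuts[pos_tested], stratum[pos_tested])
                band_vals = lo_b + rng.random(int(pos_tested.sum())) * np.maximum(hi_b - lo_b, 0.0)
                values[offsets[pos_tested]] = band_vals
            day_offset = rng.random(total) * np.repeat(los, n_meas)
            collected = pd.to_datetime(np.repeat(admit, n_meas)) + pd.to_timedelta(
                day_offset * 24 * 3600, unit="s"
            )
            meas_frames.append(
                pd.DataFrame(
                    {
                        "admission_id": admission_ids[owner],
                        "analyte": defn.analyte,
                        "value": np.round(values, 4),
                        "unit": CANONICAL_UNITS[defn.analyte],
                        "collected_at": collected.round("s"),
                    }
                )
            )

            # diagnosis coding on the logit scale
            sens = np.array(mix.coding_sensitivity, dtype=float)
            code_prob = np.full(n_adm, mix.false_positive_rate)
            pos = stratum > 0
            if pos.any():
                logits = special.logit(np.clip(sens[stratum[pos] - 1], 1e-12, 1 - 1e-12))
                logits = logits + intercepts[patient_idx[pos]] + unit_shifts[primary_unit[pos]]
                code_prob[pos] = special.expit(logits)
            coded = rng.random(n_adm) < code_prob
            if coded.any():
                diag_frames.append(
                    pd.DataFrame(
                        {
                            "admission_id": admission_ids[coded],
                            "code": defn.default_code or defn.code_set.entries[0].code,
                            "vocabulary": "ICD10",
                        }
                    )
                )
            ledger_frames.append(
                pd.DataFrame(
                    {
                        "admission_id": admission_ids,
                        "outcome": defn.outcome,
                        "stratum": np.array(STRATA)[stratum],
                        "tested": tested,
                        "coded": coded,
                        "coding_prob": code_prob,
                    }
                )
            )

    inst_names = [i.name for i in config.institutions]
    bundle = CohortBundle(
        admissions=pd.concat(adm_frames, ignore_index=True),
        measurements=pd.concat(meas_frames, ignore_index=True),
        diagnoses=(
            pd.concat(diag_frames, ignore_index=True)
            if diag_frames
            else pd.DataFrame(columns=["admission_id", "code", "vocabulary"])
        ),
        unit_stays=pd.concat(stay_frames, ignore_index=True).drop_duplicates(
            subset=["admission_id", "unit_id"], ignore_index=True
        ),
        reference_ranges=ranges.loc[ranges["institution"].isin(inst_names)].reset_index(drop=True),
    )
    ledger = pd.concat(ledger_frames, ignore_index=True)
    return bundle, ledger


# --------------------------------------------------------------------------
# Analytic oracle
# --------------------------------------------------------------------------

def _marginal_coding_probs(mix: OutcomeMix, sd: float, nodes: int = 41) -> np.ndarray:
    """Coding probability per stratum, marginal over the Gaussian patient
    intercept (Gauss-Hermite when sd > 0, exact otherwise)."""
    c = np.empty(4)
    c[0] = mix.false_positive_rate
    sens = np.clip(np.array(mix.coding_sensitivity, dtype=float), 1e-12, 1 - 1e-12)
    if sd == 0:
        c[1:] = sens
        return c
    z, w = np.polynomial.hermite.hermgauss(nodes)
    w = w / np.sqrt(np.pi)
    for s in range(3):
        c[s + 1] = float(np.sum(w * special.expit(special.logit(sens[s]) + np.sqrt(2.0) * sd * z)))
    return c


def _prob_tested(q: float, mean_extra_los: float) -> float:
    """P(at least one test) when tests are daily Bernoulli(q) over a
    1 + Poisson(mean_extra_los) day stay."""
    return 1.0 - (1.0 - q) * np.exp(-mean_extra_los * q)


def expected_metrics(
    config: SimulationConfig,
    outcome: str,
    severity: str = "mild",
    definitions: list[OutcomeDefinition] | None = None,
) -> dict[str, float]:
    """Analytic prevalence, sensitivity, specificity and kappa implied by
    a config for one outcome at one severity level.

    Institutions are pooled with weights proportional to their expected
    admission counts.  The closed form requires homogeneous units
    (``unit_acuity_sd = unit_coding_shift_sd = 0``); the patient intercept
    is integrated out by quadrature when ``intercept_sd > 0``.  ``severity``
    is one of ``mild`` / ``moderate`` / ``severe`` (lab labels whose truth
    is the latent stratum; the reference-range "abnormal" label depends on
    the range configuration and has no config-only closed form).
    """
    level = {"mild": 1, "moderate": 2, "severe": 3}.get(severity)
    if level is None:
        raise ValueError("severity must be mild, moderate or severe")
    definitions = definitions or default_outcome_definitions()
    defn = next(d for d in definitions if d.outcome == outcome)

    cells = np.zeros(4)  # [lab+ code+, lab+ code-, lab- code+, lab- code-]
    weight_total = 0.0
    for inst in config.institutions:
        if inst.unit_acuity_sd > 0 or inst.unit_coding_shift_sd > 0:
            raise ConfigError("expected_metrics requires homogeneous units")
        mix = inst.outcomes[outcome]
        p = np.array(mix.prevalence, dtype=float)
        c = _marginal_coding_probs(mix, config.intercept_sd)
        q = inst.testing_prob_per_day.get(defn.analyte, 0.5)
        t = _prob_tested(q, inst.mean_extra_los_days)
        in_label = np.array([s >= level for s in range(4)])
        in_label[0] = False
        # lab label requires the latent stratum AND an actual test draw
        p_labpos_s = p * in_label * t
        p_labneg_s = p - p_labpos_s
        w = inst.n_patients * (1.0 + inst.mean_extra_admissions)
        cells += w * np.array(
            [
                float((p_labpos_s * c).sum()),
                float((p_labpos_s * (1 - c)).sum()),
                float((p_labneg_s * c).sum()),
                float((p_labneg_s * (1 - c)).sum()),
            ]
        )
        weight_total += w
    cells /= weight_total
    p_lab = cells[0] + cells[1]
    p_code = cells[0] + cells[2]
    sens = cells[0] / p_lab if p_lab > 0 else float("nan")
    spec = cells[3] / (cells[2] + cells[3]) if cells[2] + cells[3] > 0 else float("nan")
    po = cells[0] + cells[3]
    pe = p_code * p_lab + (1 - p_code) * (1 - p_lab)
    kappa = (po - pe) / (1 - pe) if pe < 1 else float("nan")
    return {
        "prevalence": float(p_lab),
        "sensitivity": float(sens),
        "specificity": float(spec),
        "kappa": float(kappa),
    }


# --------------------------------------------------------------------------
# Scenario presets
# --------------------------------------------------------------------------

def scenario_presets() -> dict[str, SimulationConfig]:
    """Named study-condition presets shipped with the package.

    * ``null`` — two statistically identical institutions;
    * ``similar-labs-different-coding`` — identical lab-severity mixes,
      roughly ten-fold different coding-sensitivity odds;
    * ``unit-heterogeneous-coding`` — identical coding on average, but one
      institution's units apply large idiosyncratic shifts to the coding
      logit, degrading unit-level lab-vs-diagnosis correlation there.
    """
    path = resources.files("labconcord").joinpath("defaults", "presets.yaml")
    with resources.as_file(path) as p, open(p) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: SimulationConfig.from_dict(cfg)
        for name, cfg in raw.items()
        if not name.startswith("_")
    }
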