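# Methods

This note documents the models, rules and numerical choices behind
`labconcord`, and what its synthetic cohorts do and do not establish.

## Cohorts and age groups

An admission is one inpatient stay with a patient link, institution,
admit/discharge dates, age in days at admission, sex and an in-hospital
mortality flag. Eligibility follows the pediatric inclusion rule
28 days ≤ age < 18 years (neonates aged 1–27 days are excluded because
institutions differ in whether they admit healthy newborns), or age ≥ 18
years under the adult rule; the admission-date window is closed on both
ends. Multiple admissions per patient are retained — this is precisely
the correlation structure the random-intercept models address.

Ages are integer days and no birthdates exist in the schema, so year
boundaries use 365.25 days/year (configurable via `CohortConfig`). The
NICHD pediatric groups partition the eligible range at day resolution:
infant [28 d, 366 d), toddler [366 d, 3 y), early childhood [3 y, 6 y),
middle childhood [6 y, 12 y), early adolescence [12 y, 18 y). The month-
and year-denominated group names are ambiguous at their edges; each group
is taken to start where the previous named range is exceeded, and the
partition is verified exhaustively at day resolution in the tests.

## Labels

Seven outcomes are defined on seven analytes, each with a direction of
abnormality: hypercreatinemia (the lab-based measure of acute kidney
injury) and hyperkalemia use the admission **maximum** of creatinine and
potassium; the five "low" outcomes use the admission **minimum** of
glucose, sodium, ANC, hemoglobin and platelets. Units are normalized to
canonical units first (creatinine µmol/L, potassium/sodium/glucose
mmol/L, ANC and platelets 10⁹/L, hemoglobin g/L); conversion factors for
mass-unit dialects use molar masses 113.12 g/mol (creatinine) and
180.156 g/mol (glucose).

Four lab labels and one diagnosis label are produced per admission ×
outcome:

* **abnormal** — extreme value outside the institution- and
  age-group-specific reference range, on the outcome's side only (a
  hemoglobin above the high bound never triggers the anemia label);
* **mild / moderate / severe** — extreme value beyond fixed cutoffs.
  Severity is *nested*: severe ⇒ moderate ⇒ mild, enforced structurally
  by the cutoff ordering invariant. The abnormal label is independent of
  the severity ladder (reference ranges and thresholds need not agree);
* **diagnosis** — at least one diagnosis record matches the outcome's
  code set (exact or prefix match per entry).

Comparisons at cutoffs are strict (`<` for below, `>` for above): "below
the range" is read strictly, and the choice is configurable.
Admissions with no measurement of an analyte are labeled negative, not
excluded, so every denominator is the full cohort. This is a deliberate
measurement-ascertainment caveat: a lab label here means "tested and
abnormal", which is what a code-vs-lab audit can actually observe.

The shipped severity thresholds are editable defaults from common
guideline families (hypoglycemia < 3.9/3.0/2.2 mmol/L; hyponatremia
< 135/130/125 mmol/L; hyperkalemia > 5.5/6.0/6.5 mmol/L; neutropenia
< 1.5/1.0/0.5 ×10⁹/L; thrombocytopenia < 150/100/50 ×10⁹/L; anemia
< 110/90/70 g/L). Hypercreatinemia cutoffs are *relative* — 1.5×/2×/3×
the admission's age-group upper reference bound — because a single
absolute creatinine cutoff is meaningless across pediatric ages. The
engine hard-codes no threshold; everything is read from
`defaults/thresholds.yaml`. The ICD-10 prefix code sets are likewise
illustrative defaults for the audit machinery, not validated clinical
code lists.

## Concordance metrics

With the diagnosis label as test and a lab label as gold standard, each
outcome × severity level yields a 2×2 table and

* κ = (p_o − p_e)/(1 − p_e), p_o = (tp+tn)/n,
  p_e = [(tp+fn)(tp+fp) + (fp+tn)(fn+tn)]/n²;
* sensitivity tp/(tp+fn), specificity tn/(fp+tn).

κ is undefined when a margin is degenerate (p_e = 1) and ratios with
zero denominators raise explicit undefined-metric errors; summaries drop
undefined values (with a count) rather than imputing. Summaries report
both mean/SD and median/IQR/range. Display percentages round
half-away-from-zero to one decimal; raw artifacts keep full precision.

**Unit-level concordance.** "Weighted proportion" is defined by giving
each admission weight 1/k in each of the k distinct units it visited, so
every admission contributes exactly 1 in total (conservation is a tested
invariant). Per unit, the lab proportion is computed at each of the four
severity levels and then averaged; one Spearman ρ per institution ×
outcome is computed between that average and the diagnosis proportion
(midranks for ties, via `scipy.stats.spearmanr`). The alternative —
ρ per severity level, then averaged — is available behind the
`rho-then-average` flag. Weighting by unit-stay duration would be a
reasonable alternative the stay table cannot support (it has no
durations).

## Random-intercept models

Institution effects are estimated per outcome × label type (35
evaluations) from

logit P(y_ij = 1) = x_ij'β + u_j, u_j ~ N(0, σ²), patient j,

with institution and pediatric age group as fixed effects (reference:
the configured reference institution and the infant group). The marginal
likelihood integrates u_j out by **adaptive Gauss–Hermite quadrature**:
per patient, the integrand is recentred at its posterior mode with the
Laplace scale (vectorized Newton across patients), and a 15-node Hermite
rule (configurable; doubling nodes moves the institution log-OR by
< 10⁻³, a tested invariant) integrates the recentred integrand.
Maximization alternates (a) refreshing the quadrature centres and
(b) quasi-Newton steps on the fixed-centre objective, whose gradient is
analytic; the loop ends with Newton polishing (finite differences of the
analytic gradient) to a gradient-norm tolerance of 10⁻⁶. A collapsing
variance (σ below ~7·10⁻³) is pinned at its boundary and flagged
`singular`; `fix_sigma=0` profiles the fixed effects at the boundary,
the zero-variance limit in which the marginal model is an ordinary
logistic regression (this limit is verified against the plain logistic
MLE, and the free fit against R lme4's `glmer` at nAGQ = 15, in the
tests). Standard errors come from the numerically differentiated
observed information of the full adaptive-quadrature log-likelihood;
intervals are Wald (not profile), a reporting assumption, at the 99.9 %
level (z ≈ 3.2905) to temper multiple testing. Separation is detected by
coefficient divergence (|β| > 30) and reported with the offending
covariate; per-label fit failures in the 35-way analysis are recorded,
not fatal.

Testing frequency — lab tests per inpatient day, denominator
max(1, discharge − admit) days, with raw per-admission counts available
behind `per_day=False` since the quantity is described both ways in the
field — uses a linear mixed model with the same fixed effects and
patient intercept, delegated to `statsmodels.MixedLM` (REML by default).

## Synthetic cohorts and their oracles

The generator emulates the statistical structure the analysis assumes:
per institution, patients with 1 + Poisson admissions; an NICHD age-group
mix (default proportions 15.1/9.5/17.4/24.9/33.1 %, matching a large
pediatric inpatient census); lengths of stay 1 + Poisson(2) days;
per-analyte daily Bernoulli testing with institution-specific
probabilities; a latent severity stratum per admission × outcome with
lab values drawn uniformly between adjacent cutoffs (the severe band
extends one cutoff-width beyond the severe cutoff, floored at zero) and
truncated-normal values inside the reference range for non-cases — the
simplest distributions that make the labeling rules exactly invertible
for truth checking; and diagnosis codes emitted with probability
expit(logit(stratum sensitivity) + patient intercept + unit shift) for
positive strata and a flat false-positive rate otherwise. Coding
heterogeneity enters on the logit scale so the association model is
correctly specified under the generator; per-unit fixed shifts are the
deliberate misspecification toggle. Optional per-unit "acuity" shifts on
the case logit make hospital units differ in true lab prevalence, which
is what gives unit-level concordance scatter its signal. The shipped
default reference ranges are synthetic and differ between the two sites
(as real institutional ranges do) while sitting inside the severity
cutoffs, so normal-range draws never cross a severity threshold and the
closed forms below are exact.

`expected_metrics` gives the analytic prevalence, sensitivity,
specificity and κ implied by a config: with stratum probabilities p_s,
stratum coding probabilities c_s (integrated over the Gaussian patient
intercept by quadrature when σ > 0) and testing ascertainment
t = 1 − (1−q)e^{−λq} for daily probability q and stay 1 + Poisson(λ),
the 2×2 cell probabilities follow directly (a lab label requires both
the stratum and an actual test draw; coding depends on the stratum
only). It requires homogeneous units and covers the threshold-based
labels; the range-based abnormal label depends on the range
configuration and has no config-only closed form.

Three presets ship as study conditions (1,500 patients/site,
~4,800 admissions — desk-scale sizes chosen once): `null` (statistically
identical sites), `similar-labs-different-coding` (identical severity
mixes, ~10-fold different coding-sensitivity odds) and
`unit-heterogeneous-coding` (identical average coding, but one site's
units apply SD-2 logit shifts to coding; both sites use a realistic
24-unit census, as rank correlations over only a dozen units are too
noisy to characterize within-institution heterogeneity).

**What passing tests show — and don't.** The simulations verify that the
pipeline's estimators recover known generating truths: exact label
inversion, closed-form concordance on a 50,000-admission zero-variance
cohort (within 3 Monte-Carlo SEs), 99.9 % CI coverage under parameter
recovery (log-OR = log 2, σ = 1, 2,000 patients × 3 admissions), and the
qualitative signatures of coding differences. They do not establish
anything about real coding behaviour: the generator has no longitudinal
physiology, no code-co-occurrence structure, no time trends, and its
coding model (a logit-additive patient effect) is a construct. Real
reference ranges, thresholds and code lists must be supplied through the
config files for any substantive audit.

## Numerical and formatting choices

* Percentages: round half-away-from-zero, one decimal; thousands
  separators only in rendered display tables.
* κ degenerate margins, zero-denominator ratios, constant vectors in ρ:
  explicit errors, never NaN propagation inside metrics (NaN appears
  only in the tidy metric table, flagged `defined = False`).
* GLMM: 15 nodes, gradient tolerance 10⁻⁶, max 200 inner iterations,
  60 outer centre refreshes; log-σ bounded in [−10, 5].
* Reproducibility: a single integer seed drives every draw in a
  simulation; identical config + seed reproduces bundles byte for byte,
  and the CLI manifest records a config hash with no timestamps so
  re-runs are diffable.
* Acceptance-style checks in `scripts/acceptance.py` use a
  50,000-admission oracle cohort, 40 coverage replicates and 20
  heterogeneity replicates (the test suite uses 100 and 50), sizes
  chosen as the package's own desk-scale study conditions.
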