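"""Institution effects via random-intercept regression.

Repeat admissions of the same patient are correlated, so institution
effects on binary labels are estimated with a logistic regression that
adds a Gaussian random intercept per patient.  The marginal likelihood

    L(beta, sigma) = prod_g  integral N(u; 0, sigma^2)
                     prod_{i in g} expit(x_i beta + u)^{y_i}
                                   (1 - expit(x_i beta + u))^{1-y_i} du

is evaluated by adaptive Gauss-Hermite quadrature: for each patient the
integrand is recentred at its posterior mode with the Laplace scale, and
a fixed Hermite rule (default 15 nodes) integrates the recentred
integrand.  Maximization alternates updating the quadrature centres with
quasi-Newton steps on the fixed-centre objective, whose gradient is
analytic; at convergence the reported log-likelihood is the genuine
adaptive-quadrature value.

Wald intervals at the 99.9% level (z ~ 3.29) are used throughout to
temper multiple testing across the 35 outcome x label-type evaluations.
Testing frequency (lab tests per inpatient day) uses a linear mixed model
with the same fixed effects and patient random intercept (statsmodels
MixedLM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess1

from .concordance import LABEL_TYPES

__all__ = [
    "GlmmError",
    "SeparationError",
    "GlmmSpec",
    "GlmmFit",
    "fit_random_intercept_logistic",
    "fit_random_intercept_linear",
    "wald_ci",
    "or_by_institution",
    "testing_rate_table",
]

_LABEL_COLUMNS = {
    "abnormal": "lab_abnormal",
    "mild": "lab_mild",
    "moderate": "lab_moderate",
    "severe": "lab_severe",
    "diagnosis": "diagnosis_positive",
}


class GlmmError(RuntimeError):
    """Mixed-model fitting failure."""


class SeparationError(GlmmError):
    """Complete or quasi-complete separation: a covariate perfectly
    predicts the outcome and the MLE diverges."""


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification for the random-intercept fits.

    ``fixed`` columns that are non-numeric are expanded into indicator
    variables, dropping the declared reference category (or the first
    level alphabetically).
    """

    outcome: str
    fixed: tuple[str, ...] = ("institution", "age_group")
    group: str = "patient_id"
    family: str = "binomial"  # "binomial" | "gaussian"
    references: dict = field(default_factory=dict)


@dataclass
class GlmmFit:
    """Estimates from a random-intercept regression."""

    params: pd.Series  # fixed effects (log-odds or linear scale)
    se: pd.Series
    sigma_u: float  # random-intercept SD
    loglik: float
    converged: bool
    n_iter: int
    family: str
    n_obs: int
    n_groups: int
    singular: bool = False

    def wald_ci(self, name: str, level: float = 0.999) -> tuple[float, float]:
        return wald_ci(self.params[name], self.se[name], level)


def wald_ci(estimate: float, se: float, level: float) -> tuple[float, float]:
    """Symmetric Wald interval ``estimate +/- z(level) * se``.

    For odds ratios the interval is computed on the log-odds scale and
    exponentiated by the caller.  z(0.999) ~ 3.2905.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if se < 0:
        raise ValueError("se must be nonnegative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (estimate - z * se, estimate + z * se)


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------

def build_design(data: pd.DataFrame, spec: GlmmSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """(y, X, group codes, column names) from a tidy covariate table."""
    y = data[spec.outcome].to_numpy()
    cols: list[str] = ["intercept"]
    parts: list[np.ndarray] = [np.ones(len(data))]
    for col in spec.fixed:
        series = data[col]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
            parts.append(series.to_numpy(dtype=float))
            cols.append(col)
            continue
        levels = sorted(series.astype(str).unique())
        if len(levels) < 2:
            raise GlmmError(f"covariate {col!r} is constant")
        ref = str(spec.references.get(col, levels[0]))
        if ref not in levels:
            raise GlmmError(f"reference level {ref!r} absent from column {col!r}")
        for lev in levels:
            if lev == ref:
                continue
            parts.append((series.astype(str) == lev).to_numpy(dtype=float))
            cols.append(f"{col}[{lev}]")
    X = np.column_stack(parts)
    for j, name in enumerate(cols[1:], start=1):
        if np.all(X[:, j] == X[0, j]):
            raise GlmmError(f"covariate {name!r} is constant")
    groups, codes = np.unique(data[spec.group].to_numpy(), return_inverse=True)
    return y, X, codes, cols


# --------------------------------------------------------------------------
# Plain logistic (zero-variance limit and starting values)
# --------------------------------------------------------------------------

def _logistic_irls(y: np.ndarray, X: np.ndarray, cols: list[str], max_iter: int = 100) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise GlmmError("singular information matrix in logistic fit") from exc
        beta = beta + step
        if np.abs(beta).max() > 30:
            worst = cols[int(np.abs(beta).argmax())]
            raise SeparationError(
                f"separation suspected: coefficient for {worst!r} diverged"
            )
        if np.abs(step).max() < 1e-10:
            break
    return beta


# --------------------------------------------------------------------------
# Adaptive Gauss-Hermite machinery
# --------------------------------------------------------------------------

def _group_modes(
    eta0: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    sigma: float,
    u0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and Laplace scale of the random intercept per group
    (vectorized Newton iterations across groups)."""
    u = np.zeros(n_groups) if u0 is None else u0.copy()
    inv_var = 1.0 / (sigma * sigma)
    for _ in range(50):
        p = special.expit(eta0 + u[codes])
        g1 = np.bincount(codes, weights=y - p, minlength=n_groups) - u * inv_var
        g2 = -np.bincount(codes, weights=p * (1 - p), minlength=n_groups) - inv_var
        step = g1 / g2
        u -= step
        if np.abs(step).max() < 1e-11:
            break
    p = special.expit(eta0 + u[codes])
    curv = np.bincount(codes, weights=p * (1 - p), minlength=n_groups) + inv_var
    return u, 1.0 / np.sqrt(curv)


def _aghq_parts(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    z: np.ndarray,
    logw: np.ndarray,
    uhat: np.ndarray,
    scale: np.ndarray,
):
    """Log-likelihood pieces for fixed quadrature centres.

    Returns (loglik, per-node log-terms A[G,K], abscissae U[G,K], eta0).
    """
    beta, logsig = theta[:-1], theta[-1]
    sigma = np.exp(logsig)
    eta0 = X @ beta
    U = uhat[:, None] + np.sqrt(2.0) * scale[:, None] * z[None, :]  # [G,K]
    # log prior at abscissae
    log_prior = -0.5 * np.log(2 * np.pi) - logsig - 0.5 * (U / sigma) ** 2
    # conditional log-likelihood sums per group at each node
    K = z.size
    cond = np.empty((n_groups, K))
    for k in range(K):
        eta = eta0 + U[codes, k]
        ll_i = y * eta - np.logaddexp(0.0, eta)
        cond[:, k] = np.bincount(codes, weights=ll_i, minlength=n_groups)
    A = logw[None, :] + z[None, :] ** 2 + cond + log_prior
    A += 0.5 * np.log(2.0) + np.log(scale)[:, None]
    ll = float(special.logsumexp(A, axis=1).sum())
    return ll, A, U, eta0


def _fixed_centre_negloglik_grad(theta, y, X, codes, n_groups, z, logw, uhat, scale):
    ll, A, U, eta0 = _aghq_parts(theta, y, X, codes, n_groups, z, logw, uhat, scale)
    sigma = np.exp(theta[-1])
    lse = special.logsumexp(A, axis=1)
    W = np.exp(A - lse[:, None])  # node weights per group, rows sum to 1
    # beta gradient: sum_i x_i * sum_k W[g(i),k] (y_i - p_i(U[g,k]))
    r = np.zeros(len(y))
    for k in range(z.size):
        p = special.expit(eta0 + U[codes, k])
        r += W[codes, k] * (y - p)
    gbeta = X.T @ r
    # log-sigma gradient from the prior term
    gsig = float((W * ((U / sigma) ** 2 - 1.0)).sum())
    grad = np.append(gbeta, gsig)
    return -ll, -grad


def aghq_loglik(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    nodes: int,
) -> float:
    """True adaptive-quadrature marginal log-likelihood at ``theta``
    (recentres at the posterior modes for these parameters)."""
    z, w = np.polynomial.hermite.hermgauss(nodes)
    logw = np.log(w)
    beta, sigma = theta[:-1], float(np.exp(theta[-1]))
    eta0 = X @ beta
    uhat, scale = _group_modes(eta0, y, codes, n_groups, sigma)
    ll, *_ = _aghq_parts(theta, y, X, codes, n_groups, z, logw, uhat, scale)
    return ll


def fit_random_intercept_logistic(
    data: pd.DataFrame,
    spec: GlmmSpec,
    nodes: int = 15,
    tol: float = 1e-6,
    max_iter: int = 200,
    fix_sigma: float | None = None,
) -> GlmmFit:
    """Maximum-likelihood random-intercept logistic regression.

    ``nodes`` Hermite nodes (default 15) integrate the random intercept
    out of the likelihood.  Convergence requires the fixed-centre gradient
    norm below ``tol`` and stable quadrature centres.  ``fix_sigma``
    profiles the fixed effects at a held intercept SD instead of
    estimating it (``fix_sigma=0`` pins the variance at its boundary,
    the zero-variance limit in which the marginal model is an ordinary
    logistic regression).  Raises :class:`SeparationError` when a
    coefficient diverges and :class:`GlmmError` for degenerate outcomes.
    """
    y, X, codes, cols = build_design(data, spec)
    uniq = np.unique(y)
    if not np.isin(uniq, [0, 1]).all():
        raise GlmmError("outcome must be binary 0/1")
    if uniq.size < 2:
        raise GlmmError("degenerate outcome: all observations identical")
    n_groups = int(codes.max()) + 1

    beta = _logistic_irls(y.astype(float), X, cols)
    y_f = y.astype(float)
    z, w = np.polynomial.hermite.hermgauss(nodes)
    logw = np.log(w)
    if fix_sigma is None:
        theta = np.append(beta, np.log(0.5))
        bounds = [(None, None)] * X.shape[1] + [(-10.0, 5.0)]
    else:
        held = float(np.clip(np.log(max(fix_sigma, 1e-12)), -10.0, 5.0))
        theta = np.append(beta, held)
        bounds = [(None, None)] * X.shape[1] + [(held, held)]

    uhat = None
    pinned = fix_sigma is not None
    n_outer = 0
    for n_outer in range(1, 61):
        sigma = float(np.exp(theta[-1]))
        uhat, scale = _group_modes(X @ theta[:-1], y_f, codes, n_groups, sigma, uhat)
        res = optimize.minimize(
            _fixed_centre_negloglik_grad,
            theta,
            args=(y_f, X, codes, n_groups, z, logw, uhat, scale),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": max_iter, "gtol": tol / 10.0, "ftol": 1e-12},
        )
        theta_new = res.x
        if np.abs(theta_new[:-1]).max() > 30:
            worst = cols[int(np.abs(theta_new[:-1]).argmax())]
            raise SeparationError(f"separation suspected: coefficient for {worst!r} diverged")
        shift = np.abs(theta_new - theta).max()
        theta = theta_new
        if not pinned and theta[-1] <= -5.0:
            # collapsing variance: the log-sigma direction goes flat, so
            # treat as a boundary (zero-variance) fit from here on
            theta[-1] = -10.0
            bounds[-1] = (-10.0, -10.0)
            pinned = True
            continue
        if shift < 1e-6:
            break

    gnorm = np.inf
    for _ in range(3):  # refresh centres, then Newton-polish, to stationarity
        sigma = float(np.exp(theta[-1]))
        uhat, scale = _group_modes(X @ theta[:-1], y_f, codes, n_groups, sigma, uhat)
        args = (y_f, X, codes, n_groups, z, logw, uhat, scale)
        theta, gnorm = _newton_polish(theta, args, pinned, tol)
        if gnorm < max(tol, 1e-6):
            break
    converged = bool(gnorm < max(tol, 1e-6))

    loglik = aghq_loglik(theta, y_f, X, codes, n_groups, nodes)
    hess = approx_hess1(
        theta, lambda t: -aghq_loglik(t, y_f, X, codes, n_groups, nodes)
    )
    se_all = _safe_se(hess, at_bound=fix_sigma is not None or theta[-1] <= -5.0)
    params = pd.Series(theta[:-1], index=cols)
    se = pd.Series(se_all[:-1], index=cols)
    return GlmmFit(
        params=params,
        se=se,
        sigma_u=float(np.exp(theta[-1])),
        loglik=loglik,
        converged=converged,
        n_iter=n_outer,
        family="binomial",
        n_obs=len(y),
        n_groups=n_groups,
        singular=bool(theta[-1] <= -5.0),
    )


def _newton_polish(
    theta: np.ndarray, args: tuple, sigma_pinned: bool, tol: float
) -> tuple[np.ndarray, float]:
    """Newton refinement of the fixed-centre optimum (finite differences
    of the analytic gradient); returns (theta, free-gradient norm)."""

    def free_grad(t: np.ndarray) -> np.ndarray:
        g = _fixed_centre_negloglik_grad(t, *args)[1]
        return g[:-1] if sigma_pinned else g

    idx = slice(0, len(theta) - 1) if sigma_pinned else slice(None)
    g = free_grad(theta)
    for _ in range(8):
        if np.abs(g).max() < tol:
            break
        p = g.size
        H = np.empty((p, p))
        h = 1e-6
        for j in range(p):
            tp = theta.copy()
            tp[idx][j] += h  # slices of 1-D arrays are views
            H[:, j] = (free_grad(tp) - g) / h
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)) or np.abs(step).max() > 1.0:
            break
        new = theta.copy()
        new[idx] -= step
        if not sigma_pinned:
            new[-1] = np.clip(new[-1], -10.0, 5.0)
        g_new = free_grad(new)
        if np.abs(g_new).max() >= np.abs(g).max():
            break
        theta, g = new, g_new
    return theta, float(np.abs(g).max())


def _safe_se(hess: np.ndarray, at_bound: bool) -> np.ndarray:
    """Standard errors from the observed information; when the variance
    parameter sits at its boundary its row is dropped first."""
    h = hess.copy()
    if at_bound:
        h = h[:-1, :-1]
    try:
        cov = np.linalg.inv(h)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(h.shape[0], np.nan)
    if at_bound:
        se = np.append(se, np.nan)
    return se


# --------------------------------------------------------------------------
# Institution odds ratios
# --------------------------------------------------------------------------

def or_by_institution(
    labels: pd.DataFrame,
    admissions: pd.DataFrame,
    level: float = 0.999,
    reference_institution: str | None = None,
    nodes: int = 15,
    outcomes: list[str] | None = None,
    label_types: tuple[str, ...] = LABEL_TYPES,
) -> pd.DataFrame:
    """Institution odds ratio per outcome x label type.

    Fits one random-intercept logistic regression per outcome and label
    type (7 outcomes x 5 label types = 35 evaluations with the default
    definitions): label as outcome, institution and pediatric age group
    as fixed effects, patient as random intercept.  OR > 1 means higher
    odds of a positive label at the non-reference institution.  Fit
    failures are recorded (``converged = False``), not fatal.
    """
    need = {"admission_id", "patient_id", "institution", "age_group"}
    if not need.issubset(admissions.columns):
        raise ValueError(f"admissions table needs columns {sorted(need)}")
    insts = sorted(admissions["institution"].astype(str).unique())
    if len(insts) != 2:
        raise GlmmError(f"institution OR needs exactly 2 institutions, found {insts}")
    ref = reference_institution or insts[0]
    if ref not in insts:
        raise GlmmError(f"reference institution {ref!r} not present")
    other = [i for i in insts if i != ref][0]

    if outcomes is None:
        outcomes = list(pd.unique(labels["outcome"]))
    spec = GlmmSpec(
        outcome="label",
        fixed=("institution", "age_group"),
        group="patient_id",
        references={"institution": ref, "age_group": "infant"},
    )
    inst_col = f"institution[{other}]"
    rows = []
    for outcome in outcomes:
        sub = labels.loc[labels["outcome"] == outcome]
        merged = admissions.merge(sub, on="admission_id", how="inner")
        for label_type in label_types:
            data = merged[["patient_id", "institution", "age_group"]].copy()
            data["label"] = merged[_LABEL_COLUMNS[label_type]].astype(int)
            row = {
                "outcome": outcome,
                "label_type": label_type,
                "or": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "level": level,
                "converged": False,
                "note": "",
            }
            try:
                fit = fit_random_intercept_logistic(data, spec, nodes=nodes)
                lo, hi = fit.wald_ci(inst_col, level)
                row.update(
                    {
                        "or": float(np.exp(fit.params[inst_col])),
                        "ci_low": float(np.exp(lo)),
                        "ci_high": float(np.exp(hi)),
                        "converged": bool(fit.converged),
                    }
                )
            except GlmmError as exc:
                row["note"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Testing frequency (linear mixed model)
# --------------------------------------------------------------------------

def testing_rate_table(
    admissions: pd.DataFrame,
    measurements: pd.DataFrame,
    analyte: str | None = None,
    per_day: bool = True,
) -> pd.DataFrame:
    """Per-admission lab testing intensity.

    ``rate`` is the number of lab tests divided by the inpatient days
    ``max(1, discharge - admit)`` (or the raw per-admission count when
    ``per_day`` is False).
    """
    meas = measurements if analyte is None else measurements.loc[measurements["analyte"] == analyte]
    counts = meas.groupby("admission_id").size()
    out = admissions.copy()
    out["n_tests"] = out["admission_id"].map(counts).fillna(0).astype(int)
    days = (
        pd.to_datetime(out["discharge_date"]) - pd.to_datetime(out["admit_date"])
    ).dt.days.clip(lower=1)
    out["inpatient_days"] = days
    out["rate"] = out["n_tests"] / days if per_day else out["n_tests"].astype(float)
    return out


def fit_random_intercept_linear(
    data: pd.DataFrame, spec: GlmmSpec, reml: bool = True
) -> GlmmFit:
    """Random-intercept linear regression (delegates to MixedLM).

    Used for testing-frequency comparisons.  A near-zero random-intercept
    variance is flagged (``singular = True``), not fatal; a constant
    outcome yields a degenerate fit flagged the same way.
    """
    y, X, codes, cols = build_design(data, spec)
    y = y.astype(float)
    if np.allclose(y, y[0]):
        return GlmmFit(
            params=pd.Series(np.append(y[0], np.zeros(X.shape[1] - 1)), index=cols),
            se=pd.Series(np.zeros(X.shape[1]), index=cols),
            sigma_u=0.0,
            loglik=np.nan,
            converged=False,
            n_iter=0,
            family="gaussian",
            n_obs=len(y),
            n_groups=int(codes.max()) + 1,
            singular=True,
        )
    model = MixedLM(y, X, groups=codes)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, maxiter=500)
        except np.linalg.LinAlgError:
            res = model.fit(reml=reml, method="powell", maxiter=2000)
    var_u = float(np.asarray(res.cov_re)[0, 0])
    return GlmmFit(
        params=pd.Series(res.fe_params, index=cols),
        se=pd.Series(res.bse_fe, index=cols),
        sigma_u=float(np.sqrt(max(var_u, 0.0))),
        loglik=float(res.llf),
        converged=bool(res.converged),
        n_iter=0,
        family="gaussian",
        n_obs=len(y),
        n_groups=int(codes.max()) + 1,
        singular=var_u < 1e-10,
    )
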