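"""Treatment-effect estimators for re-randomisation trials.

Two analysis strategies:

* **unadjusted** — ordinary least squares of outcome on treatment (plus any
  requested covariates), treating all observations as independent.  Valid
  because clustering within patients under independent allocation is
  *ignorable*: it costs power but not type I error.
* **patient-adjusted** — a linear mixed model with a random intercept per
  patient, fitted by a profiled (RE)ML specific to the random-intercept
  structure: for a fixed variance ratio ρ = σ_u²/σ_ε² the GLS estimate, the
  residual variance and both log-determinants have closed forms, leaving a
  one-dimensional bounded optimisation.  This is numerically equivalent to a
  general mixed-model fit but orders of magnitude faster, which matters for
  Monte Carlo work.

Inference for the mixed model uses a t reference with degrees of freedom
``n_obs − n_patients − n_fixed_parameters`` (the design's small-sample df
rule); the unadjusted analysis uses standard residual df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .design import ObservationTable

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisSpec",
    "FitResult",
    "build_design_matrix",
    "fit_unadjusted",
    "fit_patient_adjusted",
    "fit",
    "mc_standard_error",
]

_COVARIATES = (
    "period_indicators",
    "prior_intervention_indicators",
    "prior_control_indicators",
    "reenrol_indicator",
)


@dataclass(frozen=True)
class AnalysisSpec:
    """What to fit: estimator family, covariate menu, test level."""

    adjust_for_patient: bool = False
    covariates: tuple[str, ...] = ()
    alpha_level: float = 0.05
    estimation: str = "reml"  # mixed model only: "reml" or "ml"
    carryover_coding: str = "indicator"  # or "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        for cov in self.covariates:
            if cov == "total_enrolments":
                raise ValueError(
                    "total_enrolments is a post-randomisation factor (it "
                    "conditions on whether the patient will require further "
                    "treatment in the future); adjusting for it biases the "
                    "treatment effect and is refused"
                )
            if cov not in _COVARIATES:
                raise ValueError(f"unknown covariate {cov!r}; choose from {_COVARIATES}")
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must lie in (0, 1)")
        if self.estimation not in ("reml", "ml"):
            raise ValueError("estimation must be 'reml' or 'ml'")
        if self.carryover_coding not in ("indicator", "linear"):
            raise ValueError("carryover_coding must be 'indicator' or 'linear'")


@dataclass
class FitResult:
    """Estimate, uncertainty and variance components from one analysis."""

    beta_hat: float
    se: float
    df: float
    p_value: float
    n_obs: int
    n_patients: int
    n_params: int
    sigma_u_sq_hat: float | None = None
    sigma_eps_sq_hat: float | None = None
    icc_hat: float | None = None
    converged: bool = True
    boundary: bool = False
    message: str = ""
    column_labels: tuple[str, ...] = ()

    def reject(self, alpha_level: float = 0.05) -> bool:
        return self.p_value < alpha_level


def mc_standard_error(p: float, replications: int) -> float:
    """Monte Carlo standard error of a simulated proportion, √(p(1−p)/R)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if replications < 1:
        raise ValueError("replications must be >= 1")
    return float(np.sqrt(p * (1.0 - p) / replications))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _indicator_block(values: np.ndarray, prefix: str) -> tuple[list[np.ndarray], list[str]]:
    levels = np.unique(values)
    cols, labels = [], []
    for lev in levels[1:]:  # reference level = smallest (0 priors / period 0)
        cols.append((values == lev).astype(float))
        labels.append(f"{prefix}[{int(lev)}]")
    return cols, labels


def build_design_matrix(
    table: ObservationTable, spec: AnalysisSpec
) -> tuple[np.ndarray, list[str]]:
    """Assemble the fixed-effects design matrix for an analysis.

    Columns: intercept, treatment, then the requested covariate blocks with
    reference level 0 (period 0 / zero prior allocations).  Blocks with a
    single observed level emit no columns; linearly dependent columns are
    dropped deterministically (left to right) with a logged note.
    """
    if not table.allocations_set:
        raise RuntimeError("allocations must be set to build a design matrix")
    n = table.n_obs
    cols = [np.ones(n), table.allocation.astype(float)]
    labels = ["intercept", "treatment"]
    for cov in spec.covariates:
        if cov == "period_indicators":
            block, names = _indicator_block(table.period - 1, "period")
        elif cov == "prior_intervention_indicators":
            if np.any(np.isnan(table.prior_intervention)):
                raise RuntimeError("carryover counts missing; compute them first")
            if spec.carryover_coding == "linear":
                block, names = [table.prior_intervention.astype(float)], ["prior_intervention"]
            else:
                block, names = _indicator_block(table.prior_intervention, "prior_intervention")
        elif cov == "prior_control_indicators":
            if np.any(np.isnan(table.prior_control)):
                raise RuntimeError("carryover counts missing; compute them first")
            if spec.carryover_coding == "linear":
                block, names = [table.prior_control.astype(float)], ["prior_control"]
            else:
                block, names = _indicator_block(table.prior_control, "prior_control")
        elif cov == "reenrol_indicator":
            block, names = [(table.total_enrolments > 1).astype(float)], ["reenrol"]
        cols.extend(block)
        labels.extend(names)

    X = np.column_stack(cols)
    # drop collinear columns deterministically, keeping earlier columns
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep: list[int] = []
        for j in range(X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > len(keep):
                keep.append(j)
        dropped = [labels[j] for j in range(X.shape[1]) if j not in keep]
        logger.info("dropping collinear design columns: %s", dropped)
        X = X[:, keep]
        labels = [labels[j] for j in keep]
    return X, labels


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def _ols_core(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    XtX = X.T @ X
    Xty = X.T @ y
    L = cho_factor(XtX, lower=True)
    beta = cho_solve(L, Xty)
    resid = y - X @ beta
    rss = float(resid @ resid)
    XtX_inv = cho_solve(L, np.eye(X.shape[1]))
    return beta, XtX_inv, rss


def fit_unadjusted(table: ObservationTable, spec: AnalysisSpec | None = None) -> FitResult:
    """OLS of outcome on treatment (model Y = α + βX + ε) plus covariates.

    With no covariates the estimate is exactly the difference in arm means.
    """
    spec = spec or AnalysisSpec()
    if spec.adjust_for_patient:
        raise ValueError("spec requests patient adjustment; use fit_patient_adjusted")
    if not table.outcomes_set:
        raise RuntimeError("outcomes must be present")
    x = table.allocation
    if (x == 1.0).sum() == 0 or (x == 0.0).sum() == 0:
        raise ValueError("one arm has zero observations")
    X, labels = build_design_matrix(table, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"fewer observations ({n}) than parameters ({p})")
    beta, XtX_inv, rss = _ols_core(X, table.outcome)
    df = n - p
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    tstat = beta[1] / se
    return FitResult(
        beta_hat=float(beta[1]),
        se=se,
        df=float(df),
        p_value=float(2.0 * stats.t.sf(abs(tstat), df)),
        n_obs=n,
        n_patients=table.n_patients,
        n_params=p,
        converged=True,
        column_labels=tuple(labels),
    )


# ---------------------------------------------------------------------------
# random-intercept mixed model (profiled REML/ML)
# ---------------------------------------------------------------------------

def _reml_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    sizes: np.ndarray,
    method: str = "reml",
):
    """Profiled (RE)ML for Y = Xβ + u + ε with a patient random intercept.

    Rows must be grouped by patient (``starts``/``sizes`` delimit blocks).
    The marginal covariance is σ_ε²·W with W = I + ρ·ZZ'; by Woodbury,
    W⁻¹ = I − c_i·J within patient i where c_i = ρ/(1 + n_i ρ).  All GLS
    cross-products reduce to per-patient sums, so each evaluation of the
    profiled objective is O(n_patients · p²).  The objective is minimised over
    h = ρ/(1+ρ) ∈ [0, 1) by bounded Brent; h = 0 is compared explicitly so the
    σ_u² = 0 boundary is honoured.
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Sx = np.add.reduceat(X, starts, axis=0)  # n_patients × p
    Sy = np.add.reduceat(y, starts)
    sizes_f = sizes.astype(float)

    def pieces(h: float):
        rho = h / (1.0 - h)
        c = rho / (1.0 + sizes_f * rho)
        A = XtX - (Sx.T * c) @ Sx          # X' W⁻¹ X
        b = Xty - Sx.T @ (c * Sy)          # X' W⁻¹ y
        q = yty - float((c * Sy) @ Sy)     # y' W⁻¹ y
        L = cho_factor(A, lower=True)
        beta = cho_solve(L, b)
        rss = q - float(b @ beta)
        logdet_W = float(np.sum(np.log1p(sizes_f * rho)))
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(L[0]))))
        return rho, beta, rss, logdet_W, logdet_A, L

    def objective(h: float) -> float:
        try:
            _, _, rss, logdet_W, logdet_A = pieces(h)[:5]
        except np.linalg.LinAlgError:
            return np.inf
        if rss <= 0:
            return np.inf
        if method == "reml":
            return (n - p) * np.log(rss) + logdet_W + logdet_A
        return n * np.log(rss) + logdet_W

    res = optimize.minimize_scalar(
        objective, bounds=(0.0, 0.999999), method="bounded",
        options={"xatol": 1e-8},
    )
    h_opt = float(res.x)
    converged = bool(res.success) and np.isfinite(res.fun)
    if objective(0.0) <= res.fun:  # boundary solution σ_u² = 0
        h_opt = 0.0
    return h_opt, pieces(h_opt), converged


def fit_patient_adjusted(
    table: ObservationTable, spec: AnalysisSpec | None = None
) -> FitResult:
    """Random-patient-intercept linear mixed model (model Y = α+βX+u_i+ε).

    REML by default; p-value from a t reference with
    df = n_obs − n_patients − n_fixed_parameters.  Boundary estimates
    (σ̂_u² = 0) and all-singleton tables fall back to the OLS fit for
    inference, flagged via ``boundary`` and ``message``.
    """
    spec = spec or AnalysisSpec(adjust_for_patient=True)
    if not table.outcomes_set:
        raise RuntimeError("outcomes must be present")
    if table.n_patients < 2:
        raise ValueError("patient-adjusted analysis needs at least 2 patients")
    X, labels = build_design_matrix(table, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"fewer observations ({n}) than parameters ({p})")

    def ols_fallback(msg: str, converged: bool = True) -> FitResult:
        beta, XtX_inv, rss = _ols_core(X, table.outcome)
        df = n - p
        sigma2 = rss / df
        se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
        tstat = beta[1] / se
        return FitResult(
            beta_hat=float(beta[1]), se=se, df=float(df),
            p_value=float(2.0 * stats.t.sf(abs(tstat), df)),
            n_obs=n, n_patients=table.n_patients, n_params=p,
            sigma_u_sq_hat=0.0, sigma_eps_sq_hat=sigma2, icc_hat=0.0,
            converged=converged, boundary=True, message=msg,
            column_labels=tuple(labels),
        )

    sizes = table.group_sizes
    if sizes.max() == 1:
        return ols_fallback(
            "all patients enrolled once: random intercept unidentified, "
            "estimator coincides with OLS"
        )

    try:
        h_opt, (rho, beta, rss, _, _, L), converged = _reml_random_intercept(
            X, table.outcome, table.group_starts, sizes, method=spec.estimation
        )
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular design: {err}") from err

    if h_opt == 0.0:
        return ols_fallback("variance ratio at boundary (sigma_u^2 = 0)",
                            converged=converged)

    denom = (n - p) if spec.estimation == "reml" else n
    sigma_eps = rss / denom
    sigma_u = rho * sigma_eps
    A_inv = cho_solve(L, np.eye(p))
    se = float(np.sqrt(sigma_eps * A_inv[1, 1]))
    df = n - table.n_patients - p
    if df <= 0:
        return ols_fallback(
            f"df rule n_obs - n_patients - n_params = {df} <= 0; "
            "reporting the OLS fit"
        )
    tstat = beta[1] / se
    if not np.isfinite(se) or not np.isfinite(beta[1]):
        return FitResult(
            beta_hat=float(beta[1]), se=se, df=float(df), p_value=np.nan,
            n_obs=n, n_patients=table.n_patients, n_params=p,
            converged=False, message="non-finite estimate",
            column_labels=tuple(labels),
        )
    return FitResult(
        beta_hat=float(beta[1]),
        se=se,
        df=float(df),
        p_value=float(2.0 * stats.t.sf(abs(tstat), df)),
        n_obs=n,
        n_patients=table.n_patients,
        n_params=p,
        sigma_u_sq_hat=float(sigma_u),
        sigma_eps_sq_hat=float(sigma_eps),
        icc_hat=float(sigma_u / (sigma_u + sigma_eps)),
        converged=converged,
        column_labels=tuple(labels),
    )


def fit(table: ObservationTable, spec: AnalysisSpec) -> FitResult:
    """Dispatch to the unadjusted or patient-adjusted estimator."""
    if spec.adjust_for_patient:
        return fit_patient_adjusted(table, spec)
    return fit_unadjusted(table, spec)
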