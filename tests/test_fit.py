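"""Estimators: OLS, the profiled-REML random-intercept model, design matrices."""

import numpy as np
import pytest
from scipy import stats

from rerand import (
    AnalysisSpec,
    OutcomeScenario,
    TrialDesign,
    build_design_matrix,
    build_scenario_design,
    build_skeleton,
    compute_carryover_counts,
    fit_patient_adjusted,
    fit_unadjusted,
    load_worked_example,
    mc_standard_error,
    randomise,
    simulate_outcomes,
    simulate_trial,
)

ADJ = AnalysisSpec(adjust_for_patient=True)


@pytest.mark.parametrize(
    "p, reps, expected",
    [
        (0.05, 5000, 0.0030822070014844882),
        (0.80, 5000, 0.005656854249492381),
        (0.0, 1234, 0.0),
    ],
)
def test_mc_standard_error(p, reps, expected):
    assert mc_standard_error(p, reps) == pytest.approx(expected, abs=1e-15)


def test_unadjusted_difference_in_means(base_trial):
    """With no covariates the OLS estimate is exactly the difference in
    arm means (closed-form oracle)."""
    res = fit_unadjusted(base_trial)
    x, y = base_trial.allocation, base_trial.outcome
    oracle = y[x == 1].mean() - y[x == 0].mean()
    assert res.beta_hat == pytest.approx(oracle, abs=1e-12)
    assert res.df == base_trial.n_obs - 2


def test_unadjusted_noiseless_exact(base_design):
    table = randomise(build_skeleton(base_design), seed=1)
    scenario = OutcomeScenario(beta=0.4, sigma_u_sq=0.0, sigma_eps_sq=0.0)
    table = simulate_outcomes(table, scenario, seed=0)
    res = fit_unadjusted(table)
    assert res.beta_hat == pytest.approx(0.4, abs=1e-12)


def test_ols_matches_normal_equations(base_trial):
    """Full coefficient vector agrees with an independent lstsq solve."""
    spec = AnalysisSpec(covariates=("period_indicators",))
    X, _ = build_design_matrix(base_trial, spec)
    res = fit_unadjusted(base_trial, spec)
    beta_oracle = np.linalg.lstsq(X, base_trial.outcome, rcond=None)[0]
    assert res.beta_hat == pytest.approx(beta_oracle[1], abs=1e-10)


def test_unadjusted_type1_error_calibration():
    """Rejection rate under the null stays within 3 MC SEs of 5%: the
    within-patient clustering is ignorable for the unadjusted analysis."""
    design, scenario = build_scenario_design("base", icc=0.5, beta=0.0)
    rng = np.random.default_rng(904)
    reps = 2000
    rej = np.empty(reps, dtype=bool)
    for r in range(reps):
        rej[r] = fit_unadjusted(simulate_trial(design, scenario, rng=rng)).reject()
    rate = rej.mean()
    assert abs(rate - 0.05) < 3 * mc_standard_error(0.05, reps)


def test_mixed_model_df_rule(base_trial):
    """df = n_obs − n_patients − n_fixed: 200 − 150 − 2 = 48."""
    res = fit_patient_adjusted(base_trial, ADJ)
    assert res.df == 48


def test_mixed_model_p_value_consistent_with_t(base_trial):
    res = fit_patient_adjusted(base_trial, ADJ)
    t = res.beta_hat / res.se
    assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), res.df), abs=1e-12)
    assert res.icc_hat == pytest.approx(
        res.sigma_u_sq_hat / (res.sigma_u_sq_hat + res.sigma_eps_sq_hat)
    )


def test_mixed_equals_ols_without_patient_effects(base_design):
    """Data generated with σu² = 0 drives the fit to the boundary, where the
    reported estimate is the OLS one."""
    design, scenario = build_scenario_design("base", icc=0.0, beta=0.4)
    table = simulate_trial(design, scenario, seed=12)
    adj = fit_patient_adjusted(table, ADJ)
    ols = fit_unadjusted(table)
    if adj.boundary:
        assert adj.beta_hat == pytest.approx(ols.beta_hat, abs=1e-12)
    else:  # a small positive variance estimate can survive sampling noise
        assert adj.beta_hat == pytest.approx(ols.beta_hat, abs=0.02)


def test_mixed_equals_ols_all_singletons():
    """Estimator equivalence: with every patient enrolled once the adjusted
    and unadjusted estimators coincide."""
    design, scenario = build_scenario_design("base", icc=0.5, beta=0.4)
    design = TrialDesign(enrolment_strata=((200, 1),))
    table = simulate_trial(design, scenario, seed=3)
    adj = fit_patient_adjusted(table, ADJ)
    ols = fit_unadjusted(table)
    assert adj.boundary
    assert adj.beta_hat == pytest.approx(ols.beta_hat, abs=1e-12)
    assert adj.se == pytest.approx(ols.se, abs=1e-12)


def _reml_objective_bruteforce(X, y, patient_codes, sigma_u_sq, sigma_eps_sq):
    """−2·REML log-likelihood via explicit marginal covariance matrices."""
    n, p = X.shape
    Z = np.zeros((n, patient_codes.max() + 1))
    Z[np.arange(n), patient_codes] = 1.0
    V = sigma_eps_sq * np.eye(n) + sigma_u_sq * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    resid = y - X @ beta
    _, logdet_V = np.linalg.slogdet(V)
    _, logdet_XtVX = np.linalg.slogdet(XtVX)
    return (
        logdet_V + logdet_XtVX + float(resid @ Vinv @ resid),
        beta,
    )


def test_reml_against_bruteforce_grid():
    """On a 6-patient, 2-period toy dataset the profiled fitter attains the
    minimum of the brute-force REML objective over a (σu², σε²) grid."""
    design, scenario = build_scenario_design("base", icc=0.5, beta=0.4)
    design = TrialDesign(enrolment_strata=((6, 2),))
    table = simulate_trial(design, scenario, seed=77)
    res = fit_patient_adjusted(table, ADJ)
    X, _ = build_design_matrix(table, ADJ)
    codes = table.patient_index

    obj_hat, beta_grid = _reml_objective_bruteforce(
        X, table.outcome, codes, res.sigma_u_sq_hat, res.sigma_eps_sq_hat
    )
    assert res.beta_hat == pytest.approx(beta_grid[1], abs=1e-8)
    # no grid point beats the returned estimates by more than the tolerance
    best = np.inf
    for su2 in np.linspace(0.0, 3.0, 121):
        for se2 in np.linspace(0.05, 3.0, 119):
            val, _ = _reml_objective_bruteforce(X, table.outcome, codes, su2, se2)
            best = min(best, val)
    assert obj_hat <= best + 1e-4


def test_reml_matches_statsmodels(base_trial):
    """Independent mixed-model route: statsmodels MixedLM agrees on the
    estimate and both variance components."""
    smf = pytest.importorskip("statsmodels.formula.api")
    df = base_trial.to_frame()
    m = smf.mixedlm("outcome ~ allocation", df, groups=df["patient_id"]).fit(
        reml=True
    )
    res = fit_patient_adjusted(base_trial, ADJ)
    assert res.beta_hat == pytest.approx(m.params["allocation"], abs=1e-5)
    assert res.sigma_u_sq_hat == pytest.approx(float(m.cov_re.iloc[0, 0]), abs=1e-4)
    assert res.sigma_eps_sq_hat == pytest.approx(m.scale, abs=1e-4)


def test_ml_estimation_available(base_trial):
    reml = fit_patient_adjusted(base_trial, ADJ)
    ml = fit_patient_adjusted(
        base_trial, AnalysisSpec(adjust_for_patient=True, estimation="ml")
    )
    # ML shrinks the residual variance relative to REML
    assert ml.sigma_eps_sq_hat < reml.sigma_eps_sq_hat * 1.001


def test_design_matrix_carryover_blocks():
    design, scenario = build_scenario_design("s7_differential_carryover", beta=0.4)
    table = simulate_trial(design, scenario, seed=21)
    spec = AnalysisSpec(
        covariates=("prior_intervention_indicators", "prior_control_indicators")
    )
    _, labels = build_design_matrix(table, spec)
    for lev in (1, 2, 3):
        assert f"prior_intervention[{lev}]" in labels
        assert f"prior_control[{lev}]" in labels


def test_design_matrix_single_period_no_indicators():
    design = TrialDesign(enrolment_strata=((50, 1),))
    table = randomise(build_skeleton(design), seed=4)
    X, labels = build_design_matrix(
        table, AnalysisSpec(covariates=("period_indicators",))
    )
    assert labels == ["intercept", "treatment"]
    assert X.shape == (50, 2)


def test_design_matrix_worked_example_membership():
    """Prior-intervention indicators reproduce the worked example's running
    count column exactly."""
    table = load_worked_example()
    X, labels = build_design_matrix(
        table, AnalysisSpec(covariates=("prior_intervention_indicators",))
    )
    for lev in (1, 2):
        col = X[:, labels.index(f"prior_intervention[{lev}]")]
        assert np.array_equal(col, (table.prior_intervention == lev).astype(float))


def test_total_enrolments_covariate_refused():
    with pytest.raises(ValueError, match="post-randomisation"):
        AnalysisSpec(covariates=("total_enrolments",))


def test_collinear_columns_dropped(base_trial):
    spec = AnalysisSpec(covariates=("period_indicators", "period_indicators"))
    X, labels = build_design_matrix(base_trial, spec)
    assert len(labels) == len(set(labels))
    assert np.linalg.matrix_rank(X) == X.shape[1]


def test_one_armed_table_rejected(base_design):
    table = build_skeleton(base_design)
    table.allocation = np.ones(table.n_obs)
    table = compute_carryover_counts(table)
    table.outcome = np.zeros(table.n_obs)
    with pytest.raises(ValueError, match="zero observations"):
        fit_unadjusted(table)
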