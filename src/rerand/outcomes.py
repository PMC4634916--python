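"""Outcome-generating models for re-randomisation trial simulations.

Outcomes follow a Gaussian random-intercept model

    Y_ij = α + β X_ij + u_i + ε_ij,   u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_ε²),

with the intraclass correlation ICC = σ_u² / (σ_u² + σ_ε²) and, throughout the
shipped study conditions, total variance σ_u² + σ_ε² fixed at 1.  Seven
scenario variants add systematic structure to the mean or to the re-enrolment
mechanism:

========  ==================================================================
base      model above, fixed enrolment design
s1        sicker patients re-randomised: + θ·Z, Z = 1 for every period of a
          multi-enrolled patient (θ = −0.5)
s2        poor first-period outcome triggers one re-enrolment (Y < −0.44,
          selecting ≈33 % of patients under the null)
s3 / s4   patients first allocated intervention / control are re-enrolled once
s5        period effect: + π·(j−1), π = 0.5 (period index 0–3)
s6        intervention carryover: + θ·A_ij, θ = 0.4
s7        differential carryover: + θ·A_ij + λ·B_ij, θ = 0.6, λ = 0.2
========  ==================================================================

A_ij / B_ij count previous allocations to intervention / control.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .design import (
    AllocationScheme,
    ObservationTable,
    TrialDesign,
    build_skeleton,
    compute_carryover_counts,
    randomise,
)

__all__ = [
    "ScenarioId",
    "OutcomeScenario",
    "IccSpec",
    "icc_to_variances",
    "simulate_outcomes",
    "apply_reenrolment_rule",
    "build_scenario_design",
    "simulate_trial",
]


class ScenarioId(str, enum.Enum):
    BASE = "base"
    S1_SICKER = "s1_sicker"
    S2_POOR_OUTCOME = "s2_poor_outcome"
    S3_INTERVENTION_REENROL = "s3_intervention_reenrol"
    S4_CONTROL_REENROL = "s4_control_reenrol"
    S5_PERIOD_EFFECT = "s5_period_effect"
    S6_INTERVENTION_CARRYOVER = "s6_intervention_carryover"
    S7_DIFFERENTIAL_CARRYOVER = "s7_differential_carryover"


_SELECTION_SCENARIOS = frozenset(
    {
        ScenarioId.S2_POOR_OUTCOME,
        ScenarioId.S3_INTERVENTION_REENROL,
        ScenarioId.S4_CONTROL_REENROL,
    }
)


@dataclass(frozen=True)
class OutcomeScenario:
    """Data-generating model identifier plus its parameters."""

    scenario_id: ScenarioId = ScenarioId.BASE
    alpha: float = 0.0
    beta: float = 0.0
    sigma_u_sq: float = 0.5
    sigma_eps_sq: float = 0.5
    theta: float = 0.0        # s1, s6, s7
    pi_coef: float = 0.0      # s5
    lambda_coef: float = 0.0  # s7
    reenrol_cutoff: float | None = None  # s2

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario_id", ScenarioId(self.scenario_id))
        if self.sigma_u_sq < 0 or self.sigma_eps_sq < 0:
            raise ValueError("variance components must be nonnegative")
        # both variances may be zero: the noiseless limit is a useful oracle
        sid = self.scenario_id
        uses_theta = sid in (
            ScenarioId.S1_SICKER,
            ScenarioId.S6_INTERVENTION_CARRYOVER,
            ScenarioId.S7_DIFFERENTIAL_CARRYOVER,
        )
        if self.theta and not uses_theta:
            raise ValueError(f"theta is unused in scenario {sid.value}")
        if self.pi_coef and sid is not ScenarioId.S5_PERIOD_EFFECT:
            raise ValueError(f"pi_coef is unused in scenario {sid.value}")
        if self.lambda_coef and sid is not ScenarioId.S7_DIFFERENTIAL_CARRYOVER:
            raise ValueError(f"lambda_coef is unused in scenario {sid.value}")
        if self.reenrol_cutoff is not None and sid is not ScenarioId.S2_POOR_OUTCOME:
            raise ValueError(f"reenrol_cutoff is unused in scenario {sid.value}")

    @property
    def icc(self) -> float:
        return self.sigma_u_sq / (self.sigma_u_sq + self.sigma_eps_sq)

    @property
    def has_selection_rule(self) -> bool:
        return self.scenario_id in _SELECTION_SCENARIOS


@dataclass(frozen=True)
class IccSpec:
    """Intraclass correlation plus total variance (default 1)."""

    icc: float
    total_variance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError("icc must lie in [0, 1]")
        if self.total_variance <= 0:
            raise ValueError("total_variance must be positive")


def icc_to_variances(spec: IccSpec | float) -> tuple[float, float]:
    """Split a total variance into (σ_u², σ_ε²) at a given ICC.

    The sum is exact: σ_u² = icc·V and σ_ε² = (1−icc)·V.
    """
    if not isinstance(spec, IccSpec):
        spec = IccSpec(icc=float(spec))
    su2 = spec.icc * spec.total_variance
    return su2, spec.total_variance - su2


def _scenario_mean(table: ObservationTable, scenario: OutcomeScenario) -> np.ndarray:
    sid = scenario.scenario_id
    mean = scenario.alpha + scenario.beta * table.allocation
    if sid is ScenarioId.S1_SICKER:
        z = (table.total_enrolments > 1).astype(float)
        mean = mean + scenario.theta * z
    elif sid is ScenarioId.S5_PERIOD_EFFECT:
        mean = mean + scenario.pi_coef * (table.period - 1)
    elif sid is ScenarioId.S6_INTERVENTION_CARRYOVER:
        mean = mean + scenario.theta * table.prior_intervention
    elif sid is ScenarioId.S7_DIFFERENTIAL_CARRYOVER:
        mean = mean + (
            scenario.theta * table.prior_intervention
            + scenario.lambda_coef * table.prior_control
        )
    return mean


def simulate_outcomes(
    table: ObservationTable,
    scenario: OutcomeScenario,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    patient_effects: dict | None = None,
    only_missing: bool = False,
) -> ObservationTable:
    """Draw outcomes for every record from the scenario's model.

    ``u_i`` is drawn once per patient and ``ε_ij`` once per record, both
    mean-zero Gaussian, independently of each other and of the allocations.
    ``patient_effects`` maps patient id → u_i for patients whose random effect
    was already drawn (used when extending a table after a re-enrolment rule);
    ``only_missing`` restricts filling to rows whose outcome is NaN.
    """
    if not table.allocations_set:
        raise RuntimeError("allocations must be set before simulating outcomes")
    needs_carryover = scenario.scenario_id in (
        ScenarioId.S6_INTERVENTION_CARRYOVER,
        ScenarioId.S7_DIFFERENTIAL_CARRYOVER,
    )
    if needs_carryover and np.any(np.isnan(table.prior_intervention)):
        raise RuntimeError("carryover counts must be computed for this scenario")
    if rng is None:
        rng = np.random.default_rng(seed)

    out = table.copy()
    starts = out.group_starts
    ids = out.patient_id[starts]
    u = rng.normal(0.0, np.sqrt(scenario.sigma_u_sq), size=len(starts))
    if patient_effects:
        for k, pid in enumerate(ids):
            if pid in patient_effects:
                u[k] = patient_effects[pid]
    u_rows = u[out.patient_index]
    eps = rng.normal(0.0, np.sqrt(scenario.sigma_eps_sq), size=out.n_obs)
    y = _scenario_mean(out, scenario) + u_rows + eps
    if only_missing:
        fill = np.isnan(out.outcome)
        out.outcome[fill] = y[fill]
    else:
        out.outcome = y
    return out


def apply_reenrolment_rule(
    table: ObservationTable,
    scenario: OutcomeScenario,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    probability: float = 0.5,
) -> ObservationTable:
    """Extend a single-period table with second periods for selected patients.

    Selection rules (all acting on the first period):

    * s2 — poor underlying response: the treatment-free component of the
      outcome (α + u_i + ε_ij, i.e. outcome minus β·X) falls below
      ``reenrol_cutoff``.  Selecting on the patient's underlying response
      rather than the realised outcome keeps the re-enrolled fraction at
      Φ(cutoff) — ≈33 % for the shipped −0.44 — in every effect mode, so the
      trial averages 200 observations whether or not the treatment works.
    * s3 — allocated to intervention,
    * s4 — allocated to control.

    New second-period records get freshly and independently randomised
    allocations (simple randomisation), recomputed carryover counts, and an
    unset outcome (fill it with :func:`simulate_outcomes` re-using the
    patients' random effects).
    """
    sid = scenario.scenario_id
    if not scenario.has_selection_rule:
        raise ValueError(f"scenario {sid.value} has no re-enrolment selection rule")
    if np.any(table.period != 1):
        raise ValueError("re-enrolment rules apply to a single-period table")
    if rng is None:
        rng = np.random.default_rng(seed)

    if sid is ScenarioId.S2_POOR_OUTCOME:
        if scenario.reenrol_cutoff is None:
            raise ValueError("scenario s2 requires reenrol_cutoff")
        if not table.outcomes_set:
            raise RuntimeError("s2 selects on first-period outcomes; simulate first")
        net_outcome = table.outcome - scenario.beta * table.allocation
        selected = net_outcome < scenario.reenrol_cutoff
    elif sid is ScenarioId.S3_INTERVENTION_REENROL:
        selected = table.allocation == 1.0
    else:
        selected = table.allocation == 0.0
    if not table.allocations_set:
        raise RuntimeError("allocations must be set before applying the rule")

    n_new = int(selected.sum())
    sel_idx = np.flatnonzero(selected)
    new_alloc = (rng.random(n_new) < probability).astype(float)

    # interleave: selected patients get a period-2 row immediately after row 1
    order_key = np.concatenate([table.patient_id, table.patient_id[sel_idx]])
    period = np.concatenate([table.period, np.full(n_new, 2, dtype=np.int64)])
    perm = np.lexsort((period, order_key))

    def merged(col_old: np.ndarray, col_new: np.ndarray) -> np.ndarray:
        return np.concatenate([col_old, col_new])[perm]

    nan_new = np.full(n_new, np.nan)
    totals = table.total_enrolments.copy()
    totals[sel_idx] = 2.0
    out = ObservationTable(
        patient_id=merged(table.patient_id, table.patient_id[sel_idx]),
        period=period[perm],
        total_enrolments=merged(totals, np.full(n_new, 2.0)),
        allocation=merged(table.allocation, new_alloc),
        prior_intervention=merged(table.prior_intervention, nan_new),
        prior_control=merged(table.prior_control, nan_new),
        outcome=merged(table.outcome, nan_new),
        time=merged(table.time, nan_new),
        design=table.design,
    )
    return compute_carryover_counts(out)


# ---------------------------------------------------------------------------
# shipped study conditions
# ---------------------------------------------------------------------------

_SCENARIO_STRATA: dict[ScenarioId, tuple[tuple[int, int], ...]] = {
    ScenarioId.BASE: ((100, 1), (50, 2)),
    ScenarioId.S1_SICKER: ((100, 1), (25, 4)),
    ScenarioId.S2_POOR_OUTCOME: ((150, 1),),
    ScenarioId.S3_INTERVENTION_REENROL: ((130, 1),),
    ScenarioId.S4_CONTROL_REENROL: ((130, 1),),
    ScenarioId.S5_PERIOD_EFFECT: ((50, 4),),
    ScenarioId.S6_INTERVENTION_CARRYOVER: ((50, 4),),
    ScenarioId.S7_DIFFERENTIAL_CARRYOVER: ((50, 4),),
}

#: Expected number of observations each scenario yields (s2–s4 on average).
SCENARIO_EXPECTED_N_OBS: dict[ScenarioId, int] = {
    ScenarioId.BASE: 200,
    ScenarioId.S1_SICKER: 200,
    ScenarioId.S2_POOR_OUTCOME: 200,
    ScenarioId.S3_INTERVENTION_REENROL: 195,
    ScenarioId.S4_CONTROL_REENROL: 195,
    ScenarioId.S5_PERIOD_EFFECT: 200,
    ScenarioId.S6_INTERVENTION_CARRYOVER: 200,
    ScenarioId.S7_DIFFERENTIAL_CARRYOVER: 200,
}


def build_scenario_design(
    scenario_id: ScenarioId | str,
    icc: float = 0.5,
    total_variance: float = 1.0,
    beta: float = 0.0,
) -> tuple[TrialDesign, OutcomeScenario]:
    """Return the study configuration for a named scenario.

    Designs and coefficients are the shipped study conditions: ICC 0.50 and
    total variance 1 throughout; θ = −0.5 (s1), re-enrolment cutoff −0.44 (s2),
    π = 0.5 (s5), θ = 0.4 (s6), θ = 0.6 and λ = 0.2 (s7).  For s2–s4 the
    design covers the initial enrolment only; the selection rule adds second
    periods at simulation time.
    """
    sid = ScenarioId(scenario_id)
    su2, se2 = icc_to_variances(IccSpec(icc=icc, total_variance=total_variance))
    design = TrialDesign(enrolment_strata=_SCENARIO_STRATA[sid])
    common = dict(scenario_id=sid, beta=beta, sigma_u_sq=su2, sigma_eps_sq=se2)
    if sid is ScenarioId.S1_SICKER:
        scenario = OutcomeScenario(theta=-0.5, **common)
    elif sid is ScenarioId.S2_POOR_OUTCOME:
        scenario = OutcomeScenario(reenrol_cutoff=-0.44, **common)
    elif sid is ScenarioId.S5_PERIOD_EFFECT:
        scenario = OutcomeScenario(pi_coef=0.5, **common)
    elif sid is ScenarioId.S6_INTERVENTION_CARRYOVER:
        scenario = OutcomeScenario(theta=0.4, **common)
    elif sid is ScenarioId.S7_DIFFERENTIAL_CARRYOVER:
        scenario = OutcomeScenario(theta=0.6, lambda_coef=0.2, **common)
    else:
        scenario = OutcomeScenario(**common)
    return design, scenario


def simulate_trial(
    design: TrialDesign,
    scenario: OutcomeScenario,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    scheme: AllocationScheme | str | None = None,
) -> ObservationTable:
    """Run the full generative pipeline for one trial replication.

    Skeleton → randomise → carryover counts → outcomes; for scenarios with a
    re-enrolment rule (s2–s4) the table is then extended and the new periods'
    outcomes are drawn re-using each patient's random effect, so that repeated
    observations stay correlated at the configured ICC.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    table = randomise(build_skeleton(design), scheme=scheme, rng=rng)
    if not scenario.has_selection_rule:
        return simulate_outcomes(table, scenario, rng=rng)

    # draw u_i up-front so first and second periods share the patient effect
    u = rng.normal(0.0, np.sqrt(scenario.sigma_u_sq), size=table.n_patients)
    effects = dict(zip(table.patient_id[table.group_starts], u))
    table = simulate_outcomes(table, scenario, rng=rng, patient_effects=effects)
    table = apply_reenrolment_rule(
        table, scenario, rng=rng,
        probability=design.allocation_probability if design else 0.5,
    )
    return simulate_outcomes(
        table, scenario, rng=rng, patient_effects=effects, only_missing=True
    )
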