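"""Trial data model, randomisation engines and design-validity checks.

A re-randomisation trial enrols *observations* rather than patients: a patient
who has completed follow-up may be independently randomised again for a new
treatment episode.  The central container is :class:`ObservationTable`, a
long-format table with one row per (patient, randomisation period).  The three
validity conditions of the design are

(a) a patient's periods do not overlap (``t_j > t_{j-1} + m``),
(b) randomisations for the same patient are mutually independent, and
(c) the treatment effect is constant across periods.

Condition (a) holds structurally for simulated tables (periods are generated
sequentially); :func:`check_validity` audits (a) and (b) on imported data.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AllocationScheme",
    "TrialDesign",
    "ObservationTable",
    "ValidityReport",
    "build_skeleton",
    "randomise",
    "compute_carryover_counts",
    "check_validity",
]


class AllocationScheme(str, enum.Enum):
    """How observations are allocated to arms.

    ``SIMPLE`` and ``PERMUTED_BLOCKS_BY_PERIOD`` satisfy condition (b)
    (a patient's allocations across periods are mutually independent).
    ``PATIENT_STRATIFIED_ALTERNATING`` deliberately violates it — each
    re-randomisation receives the complement of the previous allocation.  It is
    retained only as an anti-pattern for demonstrating the resulting bias and
    must be explicitly acknowledged (see :func:`randomise`).
    """

    SIMPLE = "simple"
    PERMUTED_BLOCKS_BY_PERIOD = "permuted_blocks_by_period"
    PATIENT_STRATIFIED_ALTERNATING = "patient_stratified_alternating"


class ConfigurationError(ValueError):
    """Invalid trial-design configuration."""


class StateError(RuntimeError):
    """Operation applied to a table in the wrong state."""


@dataclass(frozen=True)
class TrialDesign:
    """Who is enrolled how many times, and how allocation is performed.

    Parameters
    ----------
    enrolment_strata
        Sequence of ``(n_patients, periods_per_patient)`` pairs, e.g.
        ``[(100, 1), (50, 2)]`` for 100 patients randomised once and 50
        randomised twice (200 observations from 150 patients).
    allocation_scheme
        See :class:`AllocationScheme`.
    allocation_probability
        Probability of allocation to the intervention arm, in (0, 1).
    followup_length_m
        Follow-up length per randomisation period (time units); only used by
        :func:`check_validity` on tables carrying enrolment times.
    block_size
        Block size for permuted blocks (even; default 4).
    """

    enrolment_strata: tuple[tuple[int, int], ...]
    allocation_scheme: AllocationScheme = AllocationScheme.SIMPLE
    allocation_probability: float = 0.5
    followup_length_m: float | None = None
    block_size: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        strata = tuple((int(n), int(k)) for n, k in self.enrolment_strata)
        if len(strata) == 0:
            raise ConfigurationError("design needs at least one enrolment stratum")
        for n, k in strata:
            if n < 1 or k < 1:
                raise ConfigurationError(
                    f"stratum ({n}, {k}): counts and periods must be >= 1"
                )
        object.__setattr__(self, "enrolment_strata", strata)
        object.__setattr__(
            self, "allocation_scheme", AllocationScheme(self.allocation_scheme)
        )
        if not 0.0 < self.allocation_probability < 1.0:
            raise ConfigurationError("allocation_probability must lie in (0, 1)")
        if self.block_size < 2 or self.block_size % 2:
            raise ConfigurationError("block_size must be a positive even integer")

    @property
    def n_patients(self) -> int:
        return sum(n for n, _ in self.enrolment_strata)

    @property
    def n_observations(self) -> int:
        return sum(n * k for n, k in self.enrolment_strata)

    @property
    def max_periods(self) -> int:
        return max(k for _, k in self.enrolment_strata)

    def metadata(self) -> dict:
        meta = {
            "n_patients": self.n_patients,
            "n_observations": self.n_observations,
            "allocation_scheme": self.allocation_scheme.value,
        }
        if self.allocation_scheme is AllocationScheme.PATIENT_STRATIFIED_ALTERNATING:
            meta["warning"] = (
                "patient-stratified alternating allocation violates condition (b): "
                "randomisations for the same patient are not independent"
            )
        return meta


@dataclass
class ObservationTable:
    """Long-format trial data: one row per (patient, randomisation period).

    Rows are kept sorted by ``(patient_id, period)``; periods for a patient are
    consecutive starting at 1.  Unset allocations / carryover counts / outcomes
    are NaN.  Columns map onto the CSV dialect used by :mod:`rerand.io`.
    """

    patient_id: np.ndarray
    period: np.ndarray
    total_enrolments: np.ndarray
    allocation: np.ndarray
    prior_intervention: np.ndarray
    prior_control: np.ndarray
    outcome: np.ndarray
    time: np.ndarray
    design: TrialDesign | None = None
    _starts: np.ndarray = field(default=None, repr=False, compare=False)

    @classmethod
    def empty_like_design(cls, design: TrialDesign) -> "ObservationTable":
        return build_skeleton(design)

    def __post_init__(self) -> None:
        n = len(self.patient_id)
        for name in ("period", "total_enrolments", "allocation",
                     "prior_intervention", "prior_control", "outcome", "time"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has wrong length")
        self._validate_structure()

    def _validate_structure(self) -> None:
        pid, per = self.patient_id, self.period
        if len(pid) == 0:
            raise ValueError("empty observation table")
        new_patient = np.empty(len(pid), dtype=bool)
        new_patient[0] = True
        new_patient[1:] = pid[1:] != pid[:-1]
        if not np.all(per[new_patient] == 1):
            raise ValueError("each patient's periods must start at 1")
        cont = per[1:] == per[:-1] + 1
        if not np.all(new_patient[1:] | cont):
            raise ValueError("periods for a patient must be consecutive")
        if len(np.unique(pid[new_patient])) != new_patient.sum():
            raise ValueError("(patient_id, period) pairs must be unique and grouped")
        self._starts = np.flatnonzero(new_patient)

    # -- convenience ---------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.patient_id)

    @property
    def n_patients(self) -> int:
        return len(self._starts)

    @property
    def group_starts(self) -> np.ndarray:
        """Row indices where a new patient's block begins (rows are grouped)."""
        return self._starts

    @property
    def group_sizes(self) -> np.ndarray:
        return np.diff(np.append(self._starts, self.n_obs))

    @property
    def patient_index(self) -> np.ndarray:
        """0-based dense patient codes aligned with rows."""
        codes = np.zeros(self.n_obs, dtype=np.intp)
        codes[self._starts] = 1
        return np.cumsum(codes) - 1

    @property
    def allocations_set(self) -> bool:
        return not np.any(np.isnan(self.allocation))

    @property
    def outcomes_set(self) -> bool:
        return not np.any(np.isnan(self.outcome))

    def copy(self) -> "ObservationTable":
        return ObservationTable(
            patient_id=self.patient_id.copy(),
            period=self.period.copy(),
            total_enrolments=self.total_enrolments.copy(),
            allocation=self.allocation.copy(),
            prior_intervention=self.prior_intervention.copy(),
            prior_control=self.prior_control.copy(),
            outcome=self.outcome.copy(),
            time=self.time.copy(),
            design=self.design,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "period": self.period,
                "allocation": self.allocation,
                "prior_intervention": self.prior_intervention,
                "prior_control": self.prior_control,
                "total_enrolments": self.total_enrolments,
                "outcome": self.outcome,
                "time": self.time,
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, design: TrialDesign | None = None
    ) -> "ObservationTable":
        df = frame.sort_values(["patient_id", "period"], kind="stable")
        dup = df.duplicated(["patient_id", "period"])
        if dup.any():
            rows = df.loc[dup, ["patient_id", "period"]].to_records(index=False)
            raise ValueError(f"duplicate (patient_id, period) pairs: {list(rows)[:5]}")
        get = lambda col, dtype: (
            df[col].to_numpy(dtype=dtype)
            if col in df
            else np.full(len(df), np.nan)
        )
        alloc = get("allocation", float)
        finite = alloc[~np.isnan(alloc)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("allocation must be binary (0 control, 1 intervention)")
        return cls(
            patient_id=df["patient_id"].to_numpy(),
            period=df["period"].to_numpy(dtype=np.int64),
            total_enrolments=get("total_enrolments", float),
            allocation=alloc,
            prior_intervention=get("prior_intervention", float),
            prior_control=get("prior_control", float),
            outcome=get("outcome", float),
            time=get("time", float),
            design=design,
        )


@dataclass
class ValidityReport:
    """Report-only audit of design conditions (a) and (b)."""

    condition_a_ok: bool
    condition_a_violations: list[tuple]
    condition_b_pvalue: float
    notes: str = ""

    def __post_init__(self) -> None:
        assert self.condition_a_ok == (len(self.condition_a_violations) == 0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_skeleton(design: TrialDesign) -> ObservationTable:
    """Expand a :class:`TrialDesign` into an unallocated observation table.

    One record per (patient, period); patient ids run sequentially across
    strata.  Allocations, carryover counts, outcomes and times are unset.
    """
    pids, periods, totals = [], [], []
    next_id = 1
    for n, k in design.enrolment_strata:
        ids = np.arange(next_id, next_id + n)
        next_id += n
        pids.append(np.repeat(ids, k))
        periods.append(np.tile(np.arange(1, k + 1), n))
        totals.append(np.full(n * k, k, dtype=float))
    pid = np.concatenate(pids)
    n_obs = pid.size
    nan = lambda: np.full(n_obs, np.nan)
    return ObservationTable(
        patient_id=pid,
        period=np.concatenate(periods).astype(np.int64),
        total_enrolments=np.concatenate(totals),
        allocation=nan(),
        prior_intervention=nan(),
        prior_control=nan(),
        outcome=nan(),
        time=nan(),
        design=design,
    )


def _permuted_blocks(n: int, block_size: int, probability: float,
                     rng: np.random.Generator) -> np.ndarray:
    n_active = probability * block_size
    if abs(n_active - round(n_active)) > 1e-9:
        raise ConfigurationError(
            f"allocation_probability {probability} incompatible with block size "
            f"{block_size}: blocks need an integer number of intervention slots"
        )
    n_active = int(round(n_active))
    block = np.zeros(block_size)
    block[:n_active] = 1.0
    n_blocks = -(-n // block_size)
    out = np.concatenate([rng.permutation(block) for _ in range(n_blocks)])
    return out[:n]  # last incomplete block truncated after permutation


def randomise(
    table: ObservationTable,
    scheme: AllocationScheme | str | None = None,
    probability: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    acknowledge_invalid_scheme: bool = False,
) -> ObservationTable:
    """Allocate every record to intervention (1) or control (0).

    Under ``simple`` and ``permuted_blocks_by_period`` schemes a patient's
    allocations across periods are mutually independent (condition (b)).  The
    ``patient_stratified_alternating`` scheme forces each re-randomisation to
    the opposite arm and requires ``acknowledge_invalid_scheme=True``.
    """
    if table.allocations_set:
        raise StateError("table is already allocated; re-randomising is not allowed")
    if np.any(~np.isnan(table.allocation)):
        raise StateError("table is partially allocated")
    design = table.design
    scheme = AllocationScheme(
        scheme
        if scheme is not None
        else (design.allocation_scheme if design else AllocationScheme.SIMPLE)
    )
    p = probability if probability is not None else (
        design.allocation_probability if design else 0.5
    )
    if rng is None:
        rng = np.random.default_rng(seed)

    out = table.copy()
    n = out.n_obs
    if scheme is AllocationScheme.SIMPLE:
        out.allocation = (rng.random(n) < p).astype(float)
    elif scheme is AllocationScheme.PERMUTED_BLOCKS_BY_PERIOD:
        block_size = design.block_size if design else 4
        alloc = np.full(n, np.nan)
        for period in np.unique(out.period):
            idx = np.flatnonzero(out.period == period)
            alloc[idx] = _permuted_blocks(idx.size, block_size, p, rng)
        out.allocation = alloc
    elif scheme is AllocationScheme.PATIENT_STRATIFIED_ALTERNATING:
        if not acknowledge_invalid_scheme:
            raise ConfigurationError(
                "patient_stratified_alternating violates condition (b) "
                "(independent randomisations) and biases the treatment effect "
                "when re-enrolment is selective; pass "
                "acknowledge_invalid_scheme=True to use it anyway"
            )
        alloc = np.empty(n)
        first = np.zeros(n, dtype=bool)
        first[out.group_starts] = True
        alloc[first] = (rng.random(first.sum()) < p).astype(float)
        # complement of the previous period, patient by patient
        order = np.flatnonzero(~first)
        for i in order:  # rows are grouped and period-ordered
            alloc[i] = 1.0 - alloc[i - 1]
        out.allocation = alloc
    return compute_carryover_counts(out)


def compute_carryover_counts(table: ObservationTable) -> ObservationTable:
    """Fill prior-allocation counts A (intervention) and B (control).

    For the record of patient *i* in period *j*, ``A = Σ_{j'<j} X_{ij'}`` and
    ``B = (j−1) − A`` — Table-2-style running counts of previous allocations.
    """
    if not table.allocations_set:
        raise StateError("allocations must be set before computing carryover counts")
    out = table.copy()
    x = out.allocation
    cum = np.cumsum(x)
    starts = out.group_starts
    sizes = out.group_sizes
    before_group = np.repeat(cum[starts] - x[starts], sizes)
    prior = (cum - x) - before_group
    out.prior_intervention = prior
    out.prior_control = (out.period - 1) - prior
    return out


def check_validity(table: ObservationTable, m: float | None = None) -> ValidityReport:
    """Audit conditions (a) and (b) on an observation table.

    Condition (a): every re-randomisation time must satisfy
    ``t_j > t_{j-1} + m`` (skipped with a note if times are absent).
    Condition (b): chi-square independence test of allocation in period *j*
    against period *j−1*, pooled over all consecutive within-patient pairs.
    """
    notes = []
    violations: list[tuple] = []
    t = table.time
    if m is None and table.design is not None:
        m = table.design.followup_length_m
    if np.all(np.isnan(t)) or m is None:
        notes.append("condition (a) check skipped: no enrolment times / follow-up length")
    else:
        same = np.zeros(table.n_obs, dtype=bool)
        same[1:] = table.patient_id[1:] == table.patient_id[:-1]
        idx = np.flatnonzero(same)
        bad = idx[~(t[idx] > t[idx - 1] + m)]
        violations = [(table.patient_id[i], int(table.period[i])) for i in bad]

    pval = float("nan")
    if table.allocations_set:
        same = np.zeros(table.n_obs, dtype=bool)
        same[1:] = table.patient_id[1:] == table.patient_id[:-1]
        idx = np.flatnonzero(same)
        if idx.size:
            prev = table.allocation[idx - 1].astype(int)
            curr = table.allocation[idx].astype(int)
            ctab = np.zeros((2, 2))
            np.add.at(ctab, (prev, curr), 1)
            if (ctab.sum(axis=0) > 0).all() and (ctab.sum(axis=1) > 0).all():
                pval = stats.chi2_contingency(ctab, correction=False).pvalue
            else:
                notes.append("condition (b) audit degenerate: a margin is empty")
        else:
            notes.append("condition (b) audit skipped: no re-randomised patients")
    else:
        notes.append("condition (b) audit skipped: allocations unset")

    return ValidityReport(
        condition_a_ok=len(violations) == 0,
        condition_a_violations=violations,
        condition_b_pvalue=pval,
        notes="; ".join(notes),
    )
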