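"""CSV serialisation, configuration files, fixtures and run manifests.

The tabular interchange format is a plain CSV dialect with header

    patient_id,period,allocation,prior_intervention,prior_control,
    total_enrolments,outcome,time

one row per (patient, randomisation period); missing outcome/time are empty
fields.  Carryover columns are recomputed on read and cross-checked against
the file's values, warning on mismatches — a cheap integrity check on
hand-edited data.

A 16-record, 6-patient worked example of re-randomisation trial bookkeeping
(allocations with their running prior-allocation counts) ships as a named
fixture, as does the presentation tally from a sickle-cell pain-crisis centre
that motivates the design (patients present repeatedly, so a re-randomisation
design can recruit far more observations than patients).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ObservationTable, compute_carryover_counts
from .experiments import ExperimentConfig

__all__ = [
    "TRIAL_CSV_COLUMNS",
    "read_trial_csv",
    "write_trial_csv",
    "load_worked_example",
    "sickle_cell_presentation_counts",
    "load_config",
    "shipped_config_path",
    "RunManifest",
]

TRIAL_CSV_COLUMNS = (
    "patient_id",
    "period",
    "allocation",
    "prior_intervention",
    "prior_control",
    "total_enrolments",
    "outcome",
    "time",
)


def write_trial_csv(table: ObservationTable, path) -> None:
    """Write an observation table in the trial CSV dialect (RFC-4180, UTF-8)."""
    df = table.to_frame()[list(TRIAL_CSV_COLUMNS)]
    df.to_csv(path, index=False, encoding="utf-8")


def read_trial_csv(path, check_carryover: bool = True) -> ObservationTable:
    """Read a trial CSV, validating structure and carryover bookkeeping.

    Raises on duplicate (patient, period) pairs or non-binary allocations.
    When the file carries prior-allocation counts they are cross-checked
    against counts recomputed from the allocations; mismatching rows trigger a
    warning naming them, and the recomputed values win.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "period") if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing required columns: {missing}")
    table = ObservationTable.from_frame(df)
    if check_carryover and table.allocations_set:
        file_a = table.prior_intervention.copy()
        file_b = table.prior_control.copy()
        table = compute_carryover_counts(table)
        for name, file_col, new_col in (
            ("prior_intervention", file_a, table.prior_intervention),
            ("prior_control", file_b, table.prior_control),
        ):
            have = ~np.isnan(file_col)
            bad = have & (file_col != new_col)
            if bad.any():
                rows = [
                    (table.patient_id[i], int(table.period[i]))
                    for i in np.flatnonzero(bad)
                ]
                warnings.warn(
                    f"{name} in {path} disagrees with counts recomputed from "
                    f"allocations at (patient, period) {rows}; using recomputed "
                    "values",
                    stacklevel=2,
                )
    return table


def load_worked_example() -> ObservationTable:
    """The shipped 6-patient, 16-record worked example of trial bookkeeping."""
    ref = importlib.resources.files("rerand").joinpath("data/worked_example.csv")
    with importlib.resources.as_file(ref) as path:
        return read_trial_csv(path)


def sickle_cell_presentation_counts() -> dict:
    """Observed pain-crisis presentation tally from one sickle-cell centre.

    Over one year, 46 patients presented 121 times (range 1–11 per patient);
    16 patients (35 %) presented once and 30 (65 %) more than once, median 2
    presentations (IQR 1–3).  Documentation fixture only: it motivates how
    much recruitment a re-randomisation design can add, and is not used in any
    computation.
    """
    return {
        "n_patients": 46,
        "n_presentations": 121,
        "presented_once": 16,
        "presented_multiple": 30,
        "median_presentations": 2,
        "iqr_presentations": (1, 3),
        "range_presentations": (1, 11),
    }


# ---------------------------------------------------------------------------
# experiment configuration files
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ExperimentConfig)}


def shipped_config_path(name: str) -> Path:
    """Path of a shipped experiment config (table3, icc_grid, ...)."""
    ref = importlib.resources.files("rerand").joinpath(f"configs/{name}.yaml")
    with importlib.resources.as_file(ref) as path:
        if not path.exists():
            raise FileNotFoundError(f"no shipped config named {name!r}")
        return path


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment configuration from YAML or JSON.

    Unknown keys are rejected (naming the offending key); omitted keys take
    the documented defaults, including the default master seed.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of keys to values")
    unknown = sorted(set(data) - _CONFIG_FIELDS)
    if unknown:
        raise ValueError(
            f"config {path} has unknown key(s) {unknown}; "
            f"valid keys: {sorted(_CONFIG_FIELDS)}"
        )
    try:
        return ExperimentConfig(**data)
    except (TypeError, ValueError) as err:
        raise ValueError(f"config {path} is invalid: {err}") from err


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run bit-for-bit."""

    command: str
    config: dict
    master_seed: int
    package_version: str
    outputs: list[str]
    python_version: str = dataclasses.field(
        default_factory=lambda: platform.python_version()
    )

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))
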