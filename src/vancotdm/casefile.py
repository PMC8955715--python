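"""Case-file schema and format plumbing.

A case file is a YAML document with a patient block, a dosing-history block,
an optional observations block and an optional model-configuration block.
All times are decimal hours from the first infusion start; concentrations in
mg/L (identical to ug/mL).  Dosing histories and observations can also be
read from / written to CSV (columns ``time_h, dose_mg, duration_h`` and
``time_h, conc_mg_L, kind``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .bayes import ConcentrationObservation
from .pkmodel import DoseEvent, DosingHistory, PatientCovariates, PopPKModel, Regimen

__all__ = [
    "CaseFile",
    "load_case",
    "dump_case",
    "read_history_csv",
    "write_history_csv",
    "read_observations_csv",
    "write_observations_csv",
    "load_model_yaml",
]


class CaseFile(BaseModel):
    """Schema-validated TDM case: who, what was given, what was measured."""

    patient: PatientCovariates
    doses: DosingHistory
    observations: list[ConcentrationObservation] = Field(default_factory=list)
    regimen: Optional[Regimen] = None
    model: Optional[PopPKModel] = None


def load_case(path: str | Path) -> CaseFile:
    """Load and validate a YAML (or JSON) case file.

    Validation happens before any computation; missing renal data or
    out-of-range fields raise immediately.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    case = CaseFile.model_validate(data)
    t0, t_end = case.doses.span
    for o in case.observations:
        if o.time < t0:
            raise ValueError(
                f"observation at t={o.time} h precedes the first infusion"
            )
    return case


def dump_case(case: CaseFile, path: str | Path) -> None:
    path = Path(path)
    data = case.model_dump(exclude_none=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def read_history_csv(path: str | Path) -> DosingHistory:
    df = pd.read_csv(path)
    return DosingHistory(
        events=[
            DoseEvent(start_time=r.time_h, amount=r.dose_mg, duration=r.duration_h)
            for r in df.itertuples()
        ]
    )


def write_history_csv(history: DosingHistory, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"time_h": e.start_time, "dose_mg": e.amount, "duration_h": e.duration}
            for e in history.events
        ]
    ).to_csv(path, index=False)


def read_observations_csv(path: str | Path) -> list[ConcentrationObservation]:
    df = pd.read_csv(path)
    return [
        ConcentrationObservation(time=r.time_h, value=r.conc_mg_L, kind=r.kind)
        for r in df.itertuples()
    ]


def write_observations_csv(
    observations: list[ConcentrationObservation], path: str | Path
) -> None:
    pd.DataFrame(
        [{"time_h": o.time, "conc_mg_L": o.value, "kind": o.kind} for o in observations]
    ).to_csv(path, index=False)


def load_model_yaml(path: str | Path) -> PopPKModel:
    """Model configuration: every population-model field in one YAML map."""
    with open(path) as f:
        return PopPKModel(**yaml.safe_load(f))
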