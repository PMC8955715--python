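"""Initial-regimen recommendation, TDM-based dose optimization, and the
renal-function dosing nomogram.

The nomogram maps creatinine clearance (30-100 mL/min, not BSA-adjusted) and
body weight to a loading dose plus fixed daily maintenance dose chosen to
land the day-2 AUC near 400-500 ug.h/mL.  Maintenance doses are
weight-independent because clearance is driven by CLcr alone; loading doses
scale with weight to protect lean patients.  The clearance slope of the
one-compartment model is calibrated by least squares against the printed
nomogram AUC cells with V fixed at 60.7 L, which pins down the single
unprinted prior parameter.
"""

from __future__ import annotations

import importlib.resources
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field
from scipy.optimize import least_squares

from .auc import auc_model_window, auc_ss
from .pkmodel import (
    DoseEvent,
    DosingHistory,
    IndividualPK,
    PatientCovariates,
    PopPKModel,
    Regimen,
    clcr_estimate,
)

__all__ = [
    "TargetPolicy",
    "DoseRounding",
    "NomogramCell",
    "RegimenRecommendation",
    "OptimizedRegimen",
    "infusion_duration",
    "initial_regimen",
    "optimize_dose",
    "load_nomogram",
    "nomogram_history",
    "nomogram_verify",
    "calibrate_cl_slope",
    "default_model",
]


class TargetPolicy(BaseModel):
    """AUC targets used by the optimizer and the rules engine."""

    auc_band: tuple[float, float] = (400.0, 600.0)
    auc_point_target: float = 500.0
    renal_impaired_band: tuple[float, float] = (400.0, 500.0)
    day2_band_upper: float = 600.0
    mic_assumed: float = 1.0


class DoseRounding(BaseModel):
    """Rounding policy: doses may be snapped to a 0.25 g grid when the
    rounded dose stays within 2.5 mg/kg of the nominal dose."""

    per_kg_tolerance: float = 2.5
    dose_grid_mg: float = 250.0

    def round(self, nominal_mg: float, weight: float) -> float:
        snapped = self.dose_grid_mg * round(nominal_mg / self.dose_grid_mg)
        if snapped <= 0:
            snapped = self.dose_grid_mg
        if abs(snapped - nominal_mg) <= self.per_kg_tolerance * weight:
            return snapped
        return nominal_mg


class NomogramCell(BaseModel):
    """One printed nomogram entry."""

    clcr: float
    weight: float = Field(description="kg bracket")
    loading_dose_g: float
    md_dose_g: float = Field(description="single maintenance dose, g")
    md_times_per_day: int
    auc_24_48: float = Field(description="printed day-2 AUC, ug.h/mL")
    predicted_auc_24_48: Optional[float] = None

    @property
    def interval(self) -> float:
        return 24.0 / self.md_times_per_day


class RegimenRecommendation(BaseModel):
    regimen: Regimen
    warnings: list[str] = Field(default_factory=list)
    citations: list[str] = Field(default_factory=list)
    source: Literal["weight_based", "augmented_clearance", "nomogram"]


class OptimizedRegimen(BaseModel):
    regimen: Regimen
    predicted_auc_ss: float
    feasible: bool
    changed: bool
    warnings: list[str] = Field(default_factory=list)
    citations: list[str] = Field(default_factory=list)


def infusion_duration(dose_mg: float) -> float:
    """Infusion duration in hours: 30 min per 0.5 g with a 1 h floor (slow
    administration prevents infusion-related reactions)."""
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    return max(1.0, dose_mg / 1000.0)


def initial_regimen(
    patient: PatientCovariates,
    policy: Optional[TargetPolicy] = None,
    rounding: Optional[DoseRounding] = None,
    model: Optional[PopPKModel] = None,
) -> RegimenRecommendation:
    """Recommend the initial regimen from weight and renal function.

    Normal renal function: loading dose 30 mg/kg then maintenance 20 mg/kg
    q12h (preset B-2).  Augmented clearance (eGFR >= 130 mL/min/1.73 m2):
    maintenance 20 mg/kg q8h.  Impaired kidney function (CLcr < 60 mL/min):
    nomogram lookup.  Doses are nominal weight-based amounts; pass a
    ``rounding`` policy to snap onto the 0.25 g grid within 2.5 mg/kg.
    Warnings flag a loading dose > 3 g and a daily dose > 4 g.
    """
    weight = patient.weight
    citations: list[str] = []
    warnings: list[str] = []

    clcr = clcr_estimate(patient)  # raises if renal function unavailable

    if patient.egfr is not None and patient.egfr >= 130.0:
        ld = 30.0 * weight
        md = 20.0 * weight
        interval = 8.0
        source = "augmented_clearance"
        citations += ["CQ9(1a)", "CQ9(1c)"]
    elif clcr < 60.0:
        cell = _nomogram_lookup(clcr, weight)
        ld = cell.loading_dose_g * 1000.0
        md = cell.md_dose_g * 1000.0
        interval = cell.interval
        source = "nomogram"
        citations += ["CQ10(1a)"]
    else:
        ld = 30.0 * weight
        md = 20.0 * weight
        interval = 12.0
        source = "weight_based"
        citations += ["CQ9(1a)", "CQ9(1b)"]

    if rounding is not None:
        ld = rounding.round(ld, weight)
        md = rounding.round(md, weight)

    if ld > 3000.0:
        warnings.append("loading dose exceeds 3 g: few safety data [CQ9(1a)]")
    daily = md * 24.0 / interval
    if daily > 4000.0:
        warnings.append("daily dose exceeds 4 g: use carefully [CQ9(1b)]")

    regimen = Regimen(
        loading_dose=ld,
        maintenance_dose=md,
        interval=interval,
        preset_name="B-2" if source == "weight_based" and rounding is None else None,
    )
    return RegimenRecommendation(
        regimen=regimen, warnings=warnings, citations=citations, source=source  # type: ignore[arg-type]
    )


def _nomogram_lookup(clcr: float, weight: float) -> NomogramCell:
    """Nearest printed nomogram cell by CLcr row then weight bracket."""
    cells = load_nomogram()
    rows = sorted({c.clcr for c in cells})
    row = min(rows, key=lambda r: abs(r - clcr))
    in_row = [c for c in cells if c.clcr == row]
    return min(in_row, key=lambda c: abs(c.weight - weight))


# --- dose optimization -----------------------------------------------------

_DOSE_GRID = np.arange(250.0, 2000.0 + 1, 250.0)
_INTERVALS = (24.0, 12.0, 8.0)  # fewer daily administrations first


def optimize_dose(
    ind: IndividualPK,
    policy: Optional[TargetPolicy] = None,
    current: Optional[Regimen] = None,
    dose_grid: Optional[Sequence[float]] = None,
    intervals: Optional[Sequence[float]] = None,
    daily_dose_cap: float = 4000.0,
) -> OptimizedRegimen:
    """Pick the maintenance regimen whose steady-state 24-h AUC is closest
    to the 500 ug.h/mL point target.

    Exhaustive search over the discrete grid (doses 250-2000 mg by 250 mg,
    intervals 8/12/24 h); ties break toward fewer daily administrations,
    then the lower daily dose.  A current regimen already on target is kept
    unchanged.  If no grid point lands inside the 400-600 band the nearest
    regimen is returned flagged infeasible.
    """
    policy = policy or TargetPolicy()
    doses = np.asarray(dose_grid if dose_grid is not None else _DOSE_GRID, dtype=float)
    taus = tuple(intervals) if intervals is not None else _INTERVALS
    target = policy.auc_point_target
    lo, hi = policy.auc_band

    def score(dose: float, tau: float) -> tuple[float, float, float]:
        daily = dose * 24.0 / tau
        auc = daily / ind.cl
        # lexicographic: |AUC - target|, administrations/day, daily dose
        return (abs(auc - target), 24.0 / tau, daily)

    best: Optional[tuple[float, float]] = None
    best_key: Optional[tuple[float, float, float]] = None
    for tau in taus:
        for dose in doses:
            key = score(dose, tau)
            if best_key is None or key < best_key:
                best, best_key = (float(dose), tau), key
    assert best is not None and best_key is not None

    changed = True
    if current is not None:
        cur_key = score(current.maintenance_dose, current.interval)
        if cur_key[0] <= best_key[0]:
            best = (current.maintenance_dose, current.interval)
            best_key = cur_key
            changed = False

    dose, tau = best
    daily = dose * 24.0 / tau
    auc = daily / ind.cl
    warnings = []
    if daily > daily_dose_cap:
        warnings.append(f"daily dose {daily:.0f} mg exceeds {daily_dose_cap:.0f} mg cap")
    regimen = Regimen(
        loading_dose=current.loading_dose if current is not None else None,
        maintenance_dose=dose,
        interval=tau,
    )
    return OptimizedRegimen(
        regimen=regimen,
        predicted_auc_ss=auc,
        feasible=lo <= auc <= hi,
        changed=changed,
        warnings=warnings,
        citations=["CQ9(2a)", "CQ9(2b)"],
    )


# --- nomogram verification and calibration ---------------------------------

def load_nomogram() -> list[NomogramCell]:
    """The printed nomogram cells shipped with the package."""
    with importlib.resources.files("vancotdm.data").joinpath("nomogram.csv").open() as f:
        df = pd.read_csv(f)
    return [
        NomogramCell(
            clcr=r.clcr,
            weight=r.weight_kg,
            loading_dose_g=r.loading_dose_g,
            md_dose_g=r.md_dose_g,
            md_times_per_day=int(r.md_times_per_day),
            auc_24_48=r.auc_24_48,
        )
        for r in df.itertuples()
    ]


def nomogram_history(cell: NomogramCell, horizon_h: float = 48.0) -> DosingHistory:
    """Dosing history for one nomogram cell: loading dose at t = 0, then
    maintenance q12h from t = 12 h, or q24h from t = 24 h (the first
    calendar day of a once-daily schedule carries the loading dose only).
    Infusion durations follow the 30 min / 0.5 g rule with a 1 h floor.
    """
    ld_mg = cell.loading_dose_g * 1000.0
    md_mg = cell.md_dose_g * 1000.0
    events = [DoseEvent(start_time=0.0, amount=ld_mg, duration=infusion_duration(ld_mg))]
    t = cell.interval
    md_dur = infusion_duration(md_mg)
    while t < horizon_h:
        events.append(DoseEvent(start_time=t, amount=md_mg, duration=md_dur))
        t += cell.interval
    return DosingHistory(events=events)


def _predict_cell_auc(model: PopPKModel, cell: NomogramCell) -> float:
    from .pkmodel import population_cl

    ind = IndividualPK.from_population(model, cell.clcr)
    return auc_model_window(ind, nomogram_history(cell), 24.0, 48.0)


def nomogram_verify(
    model: PopPKModel, cells: Optional[Sequence[NomogramCell]] = None
) -> pd.DataFrame:
    """Forward-simulate every nomogram cell and tabulate predicted vs
    printed day-2 AUC with relative residuals."""
    cells = list(cells) if cells is not None else load_nomogram()
    rows = []
    for cell in cells:
        pred = _predict_cell_auc(model, cell)
        cell.predicted_auc_24_48 = pred
        rows.append(
            {
                "clcr": cell.clcr,
                "weight_kg": cell.weight,
                "loading_dose_g": cell.loading_dose_g,
                "md_dose_g": cell.md_dose_g,
                "md_times_per_day": cell.md_times_per_day,
                "auc_printed": cell.auc_24_48,
                "auc_predicted": pred,
                "rel_residual": (pred - cell.auc_24_48) / cell.auc_24_48,
            }
        )
    return pd.DataFrame(rows)


def calibrate_cl_slope(
    cells: Optional[Sequence[NomogramCell]] = None,
    v_pop: float = 60.7,
    fit_intercept: bool = False,
    x0_slope: float = 0.05,
) -> tuple[PopPKModel, pd.DataFrame]:
    """Least-squares fit of the renal clearance slope (optionally plus an
    intercept) against the printed nomogram AUC cells, with V fixed.

    Returns the calibrated model and the residual table from
    :func:`nomogram_verify`.  The inverse problem is well conditioned: at
    steady state AUC ~ daily dose / (slope * CLcr), so each cell bounds the
    slope directly.
    """
    cells = list(cells) if cells is not None else load_nomogram()
    printed = np.array([c.auc_24_48 for c in cells])

    def residuals(theta: np.ndarray) -> np.ndarray:
        model = PopPKModel(
            theta_cl_slope=float(theta[0]),
            theta_cl_intercept=float(theta[1]) if fit_intercept else 0.0,
            v_pop=v_pop,
        )
        pred = np.array([_predict_cell_auc(model, c) for c in cells])
        return pred - printed

    x0 = np.array([x0_slope, 0.0]) if fit_intercept else np.array([x0_slope])
    sol = least_squares(residuals, x0, method="lm")
    model = PopPKModel(
        theta_cl_slope=float(sol.x[0]),
        theta_cl_intercept=float(sol.x[1]) if fit_intercept else 0.0,
        v_pop=v_pop,
    )
    return model, nomogram_verify(model, cells)


def default_model() -> PopPKModel:
    """The calibrated population model shipped as configuration data."""
    with importlib.resources.files("vancotdm.data").joinpath(
        "default_model.yaml"
    ).open() as f:
        cfg = yaml.safe_load(f)
    return PopPKModel(**cfg)
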