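"""One-compartment intravenous-infusion population PK model of vancomycin.

Structural model: single compartment of volume V (L), zero-order infusion
input, first-order elimination with rate constant k = CL/V.  Concentrations
are superpositions of the closed-form single-infusion solution

    during infusion (0 <= dt <= D):  C = (R0/CL) * (1 - exp(-k*dt))
    after infusion   (dt > D):       C = (R0/CL) * (1 - exp(-k*D))
                                         * exp(-k*(dt - D))

with R0 = amount/D.  Clearance is a linear function of creatinine clearance
(capped), volume is a population constant, and between-subject variability
acts log-normally on both.

Units: time h, amount mg, volume L, clearance L/h, concentration mg/L
(identical to ug/mL).
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "RiskFlags",
    "PatientCovariates",
    "PopPKModel",
    "DoseEvent",
    "DosingHistory",
    "Regimen",
    "IndividualPK",
    "RenalFunctionUnavailableError",
    "clcr_estimate",
    "population_cl",
    "concentration",
    "amount_in_body",
]

#: Renal clearance slope (L/h per mL/min CLcr) reproducing the published
#: day-2 AUC nomogram with V = 60.7 L.  Obtained by
#: :func:`vancotdm.dosing.calibrate_cl_slope`; stored in
#: ``data/default_model.yaml`` and kept here only as a fallback default.
DEFAULT_CL_SLOPE = 0.0496095


class RenalFunctionUnavailableError(ValueError):
    """Raised when renal dosing is requested but neither serum creatinine
    nor a measured creatinine clearance is available."""


class RiskFlags(BaseModel):
    """Risk-factor flags feeding the AKI-risk classification and the
    TDM-timing rules."""

    icu: bool = False
    piperacillin_tazobactam: bool = False
    diuretics: bool = False
    other_nephrotoxins: bool = False
    serious_infection: bool = False


class PatientCovariates(BaseModel):
    """Demographics and renal function of one adult patient.

    ``clcr_measured`` is a measured creatinine clearance in mL/min, *not*
    adjusted to 1.73 m2 body surface area; ``egfr`` (mL/min/1.73 m2) is used
    only by the rules engine (augmented-clearance and AKI-risk thresholds),
    never inside the PK model.
    """

    age: float = Field(gt=0, description="years")
    weight: float = Field(gt=0, description="actual body weight, kg")
    sex: Literal["male", "female"]
    serum_creatinine: Optional[float] = Field(default=None, gt=0, description="mg/dL")
    clcr_measured: Optional[float] = Field(default=None, gt=0, description="mL/min")
    egfr: Optional[float] = Field(default=None, gt=0, description="mL/min/1.73m2")
    flags: RiskFlags = Field(default_factory=RiskFlags)


class PopPKModel(BaseModel):
    """Population prior: CL = intercept + slope * min(CLcr, cap), V = v_pop,
    log-normal between-subject effects, proportional + additive residual."""

    theta_cl_slope: float = Field(default=DEFAULT_CL_SLOPE, gt=0)
    theta_cl_intercept: float = 0.0
    v_pop: float = Field(default=60.7, gt=0)
    omega2_cl: float = Field(default=0.35**2, ge=0)
    omega2_v: float = Field(default=0.25**2, ge=0)
    sigma_prop: float = Field(default=0.10, ge=0)
    sigma_add: float = Field(default=0.5, ge=0)
    clcr_cap: float = Field(default=130.0, gt=0)


class DoseEvent(BaseModel):
    """One zero-order intravenous infusion."""

    start_time: float = Field(ge=0, description="h from therapy start")
    amount: float = Field(gt=0, description="mg")
    duration: float = Field(gt=0, description="h")

    @property
    def rate(self) -> float:
        """Infusion rate R0, mg/h."""
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


class DosingHistory(BaseModel):
    """Ordered list of infusion events; times are absolute hours from the
    first infusion start (t = 0)."""

    events: list[DoseEvent]

    @model_validator(mode="after")
    def _sort(self) -> "DosingHistory":
        self.events.sort(key=lambda e: e.start_time)
        return self

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, amounts, durations) as float arrays."""
        if not self.events:
            z = np.zeros(0)
            return z, z.copy(), z.copy()
        return (
            np.array([e.start_time for e in self.events]),
            np.array([e.amount for e in self.events]),
            np.array([e.duration for e in self.events]),
        )

    @property
    def span(self) -> tuple[float, float]:
        """(first infusion start, last infusion end)."""
        if not self.events:
            return (0.0, 0.0)
        return (self.events[0].start_time, max(e.end_time for e in self.events))

    def total_infused(self, t1: float, t2: float) -> float:
        """Drug amount (mg) infused in the window (t1, t2], prorating
        infusions that straddle a boundary."""
        total = 0.0
        for e in self.events:
            overlap = min(t2, e.end_time) - max(t1, e.start_time)
            if overlap > 0:
                total += e.rate * overlap
        return total


_PRESETS = {
    # name: (loading mg/kg or None, maintenance mg/kg, interval h)
    "A-1": (None, 15.0, 12.0),
    "A-2": (None, 20.0, 12.0),
    "B-1": (25.0, 15.0, 12.0),
    "B-2": (30.0, 20.0, 12.0),
}


class Regimen(BaseModel):
    """Loading dose + repeating maintenance schedule.

    ``first_maintenance_time`` defaults to one interval after the loading
    dose (or t = 0 when there is no loading dose).
    """

    loading_dose: Optional[float] = Field(default=None, gt=0, description="mg")
    maintenance_dose: float = Field(gt=0, description="mg")
    interval: float = Field(default=12.0, description="h")
    first_maintenance_time: Optional[float] = Field(default=None, ge=0)
    n_days: int = Field(default=4, gt=0)
    preset_name: Optional[Literal["A-1", "A-2", "B-1", "B-2"]] = None

    @classmethod
    def from_preset(
        cls, name: str, weight: float, n_days: int = 4
    ) -> "Regimen":
        """Named guideline regimens: per-kg loading/maintenance doses on a
        12-hourly schedule (A-1: 15 mg/kg, A-2: 20 mg/kg, B-1: 25+15 mg/kg,
        B-2: 30+20 mg/kg)."""
        if name not in _PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
        ld_per_kg, md_per_kg, interval = _PRESETS[name]
        return cls(
            loading_dose=None if ld_per_kg is None else ld_per_kg * weight,
            maintenance_dose=md_per_kg * weight,
            interval=interval,
            preset_name=name,  # type: ignore[arg-type]
            n_days=n_days,
        )

    @property
    def daily_dose(self) -> float:
        """Maintenance drug mass per 24 h, mg."""
        return self.maintenance_dose * 24.0 / self.interval

    def to_history(self, n_days: Optional[int] = None) -> DosingHistory:
        """Expand into explicit infusion events over ``n_days`` days.

        Infusion durations follow the administration-rate rule (30 min per
        0.5 g with a 1 h floor).
        """
        from .dosing import infusion_duration  # local import avoids a cycle

        horizon = 24.0 * (n_days if n_days is not None else self.n_days)
        events: list[DoseEvent] = []
        if self.loading_dose is not None:
            events.append(
                DoseEvent(
                    start_time=0.0,
                    amount=self.loading_dose,
                    duration=infusion_duration(self.loading_dose),
                )
            )
            first = (
                self.first_maintenance_time
                if self.first_maintenance_time is not None
                else self.interval
            )
        else:
            first = (
                self.first_maintenance_time
                if self.first_maintenance_time is not None
                else 0.0
            )
        md_dur = infusion_duration(self.maintenance_dose)
        t = first
        while t < horizon:
            events.append(
                DoseEvent(start_time=t, amount=self.maintenance_dose, duration=md_dur)
            )
            t += self.interval
        return DosingHistory(events=events)


class IndividualPK(BaseModel):
    """Individual clearance/volume with the log-scale deviations that
    produced them: cl = CL_pop * exp(eta_cl), v = v_pop * exp(eta_v)."""

    cl: float = Field(gt=0, description="L/h")
    v: float = Field(gt=0, description="L")
    eta_cl: float = 0.0
    eta_v: float = 0.0

    @classmethod
    def from_population(
        cls,
        model: PopPKModel,
        clcr: float,
        eta_cl: float = 0.0,
        eta_v: float = 0.0,
    ) -> "IndividualPK":
        cl_pop = population_cl(model, clcr)
        return cls(
            cl=cl_pop * float(np.exp(eta_cl)),
            v=model.v_pop * float(np.exp(eta_v)),
            eta_cl=eta_cl,
            eta_v=eta_v,
        )

    @property
    def k(self) -> float:
        """Elimination rate constant, 1/h."""
        return self.cl / self.v


def clcr_estimate(patient: PatientCovariates) -> float:
    """Creatinine clearance in mL/min.

    A measured value is returned verbatim.  Otherwise Cockcroft-Gault on
    actual body weight: (140 - age) * weight / (72 * Scr), x0.85 for women.
    No body-surface-area adjustment is applied.
    """
    if patient.clcr_measured is not None:
        return patient.clcr_measured
    if patient.serum_creatinine is None:
        raise RenalFunctionUnavailableError(
            "renal function unavailable: provide serum_creatinine or clcr_measured"
        )
    clcr = (140.0 - patient.age) * patient.weight / (72.0 * patient.serum_creatinine)
    if patient.sex == "female":
        clcr *= 0.85
    return clcr


def population_cl(model: PopPKModel, clcr: float) -> float:
    """Population clearance CL_pop = intercept + slope * min(CLcr, cap), L/h."""
    if clcr <= 0:
        raise ValueError("clcr must be positive")
    cl = model.theta_cl_intercept + model.theta_cl_slope * min(clcr, model.clcr_cap)
    if cl <= 0:
        raise ValueError(
            f"configured model yields non-positive clearance ({cl:.4g} L/h) "
            f"at CLcr {clcr:.4g} mL/min"
        )
    return cl


def _profile(t, cl, v, starts, amounts, durations):
    """Superposed single-infusion solutions, vectorized over ``t``.

    ``cl`` and ``v`` may be complex (complex-step differentiation in the MAP
    objective); the piecewise branching depends only on the real time axis,
    along which the solution is analytic inside each piece.
    """
    t = np.asarray(t, dtype=float)
    k = cl / v
    out = np.zeros(t.shape, dtype=np.result_type(cl, v, float))
    for ts, amt, d in zip(starts, amounts, durations):
        r0 = amt / d
        dt = t - ts
        during = (dt >= 0) & (dt <= d)
        post = dt > d
        if np.any(during):
            out[during] += (r0 / cl) * (1.0 - np.exp(-k * dt[during]))
        if np.any(post):
            out[post] += (
                (r0 / cl) * (1.0 - np.exp(-k * d)) * np.exp(-k * (dt[post] - d))
            )
    return out


def concentration(ind: IndividualPK, doses: DosingHistory, t) -> np.ndarray | float:
    """Serum concentration C(t) in mg/L at time(s) ``t`` (absolute hours).

    Non-negative, linear in the dose amounts, and zero before the first
    infusion starts.
    """
    starts, amounts, durations = doses.arrays()
    scalar = np.isscalar(t)
    c = _profile(np.atleast_1d(np.asarray(t, dtype=float)), ind.cl, ind.v,
                 starts, amounts, durations)
    c = np.real(c)
    return float(c[0]) if scalar else c


def amount_in_body(ind: IndividualPK, doses: DosingHistory, t) -> np.ndarray | float:
    """Drug amount in the body A(t) = C(t) * V, mg."""
    c = concentration(ind, doses, t)
    return c * ind.v
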