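"""AUC computation.

Model-based AUCs over arbitrary windows use mass balance rather than
quadrature: for a one-compartment model, integrating dA/dt = in(t) - CL*C
over [t1, t2] gives

    AUC(t1, t2) = (A(t1) + dose infused in (t1, t2] - A(t2)) / CL,

exact up to floating point.  Day 1 is the window [0, 24] h and day 2 is
[24, 48] h from the first infusion start; the steady-state 24-h AUC of a
repeating regimen is daily maintenance dose / CL.

Observation-based AUC uses the linear-up/log-down trapezoid: rising or flat
segments use the linear trapezoid, falling segments with positive endpoints
use dt * (C1 - C2) / ln(C1/C2) (exact on mono-exponential decay), and a fall
to zero falls back to linear.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .pkmodel import DosingHistory, IndividualPK, Regimen, amount_in_body

__all__ = [
    "AUCReport",
    "auc_model_window",
    "auc_ss",
    "auc_trapezoid_linlog",
    "steady_state_trough_peak",
    "auc_report",
]


class AUCReport(BaseModel):
    """Day-1 / day-2 / steady-state exposure summary for one patient."""

    auc_0_24: float = Field(ge=0, description="ug.h/mL")
    auc_24_48: float = Field(ge=0, description="ug.h/mL")
    auc_ss_24: Optional[float] = Field(default=None, ge=0, description="ug.h/mL")
    trough_ss: Optional[float] = Field(default=None, ge=0, description="mg/L")
    peak_ss: Optional[float] = Field(default=None, ge=0, description="mg/L")
    method: Literal["model", "trapezoid"] = "model"


def auc_model_window(
    ind: IndividualPK, doses: DosingHistory, t1: float, t2: float
) -> float:
    """Model AUC over (t1, t2] by mass balance, ug.h/mL."""
    if not t2 > t1 or t1 < 0:
        raise ValueError("window must satisfy t2 > t1 >= 0")
    if not doses.events:
        return 0.0
    a1 = amount_in_body(ind, doses, t1)
    a2 = amount_in_body(ind, doses, t2)
    infused = doses.total_infused(t1, t2)
    return (a1 + infused - a2) / ind.cl


def auc_ss(ind: IndividualPK, regimen: Regimen) -> float:
    """Steady-state AUC over 24 h: daily maintenance dose / CL.

    Exact by superposition for any repeating schedule; independent of the
    loading dose, which washes out.
    """
    return regimen.daily_dose / ind.cl


def steady_state_trough_peak(ind: IndividualPK, regimen: Regimen) -> tuple[float, float]:
    """(trough, peak) concentrations of the repeating maintenance schedule
    at steady state, mg/L.

    Trough is the concentration immediately before a dose; peak is at the
    end of the infusion.  Closed form for interval tau, infusion duration D:

        peak   = (R0/CL) (1 - e^{-kD}) / (1 - e^{-k tau})
        trough = peak * e^{-k (tau - D)}
    """
    from .dosing import infusion_duration

    tau = regimen.interval
    d = infusion_duration(regimen.maintenance_dose)
    k = ind.k
    r0 = regimen.maintenance_dose / d
    accum = 1.0 / (1.0 - np.exp(-k * tau))
    peak = (r0 / ind.cl) * (1.0 - np.exp(-k * d)) * accum
    trough = peak * np.exp(-k * (tau - d))
    return float(trough), float(peak)


def auc_trapezoid_linlog(samples: Sequence[tuple[float, float]]) -> float:
    """Linear-up/log-down trapezoidal AUC from (time, concentration) pairs.

    The reference method for rich-sampling AUC: linear trapezoid on rising
    or flat segments, logarithmic trapezoid on falling segments with both
    concentrations positive, linear fallback when the curve falls to zero.
    """
    if len(samples) < 2:
        raise ValueError("at least 2 samples required")
    t = np.array([s[0] for s in samples], dtype=float)
    c = np.array([s[1] for s in samples], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    total = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c2 > 0:
            total += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            total += dt * (c1 + c2) / 2.0
    return float(total)


def auc_report(
    ind: IndividualPK,
    doses: DosingHistory,
    regimen: Optional[Regimen] = None,
) -> AUCReport:
    """Full exposure report: day-1 and day-2 AUC from the dosing history,
    plus steady-state AUC/trough/peak when the repeating regimen is known."""
    rep = AUCReport(
        auc_0_24=auc_model_window(ind, doses, 0.0, 24.0) if doses.events else 0.0,
        auc_24_48=auc_model_window(ind, doses, 24.0, 48.0) if doses.events else 0.0,
        method="model",
    )
    if regimen is not None:
        rep.auc_ss_24 = auc_ss(ind, regimen)
        trough, peak = steady_state_trough_peak(ind, regimen)
        rep.trough_ss = trough
        rep.peak_ss = peak
    return rep
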