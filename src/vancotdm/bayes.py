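"""MAP-Bayesian estimation of individual vancomycin PK from sparse levels.

Given a population prior (log-normal between-subject variability on CL and
V) and measured concentrations at their *exact* sampling times, the
posterior mode of eta = (eta_CL, eta_V) minimizes

    J(eta) = sum_i (C_obs,i - C_pred,i(eta))^2 / var_i  +  eta' Omega^-1 eta,
    var_i  = (sigma_prop * C_pred,i)^2 + sigma_add^2.

The objective is smooth in eta, so gradients are computed by complex-step
differentiation of the closed-form concentration solution (machine-precision
derivatives, no finite-difference truncation).  Optimization is
deterministic: L-BFGS-B multi-start from eta = 0 plus four fixed
perturbations, the best objective wins, ties broken toward the smallest
||eta||.  With no observations the prior mode (eta = 0) is returned exactly.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy.optimize import minimize

from .auc import AUCReport, auc_report
from .pkmodel import (
    DosingHistory,
    IndividualPK,
    PatientCovariates,
    PopPKModel,
    Regimen,
    _profile,
    clcr_estimate,
    population_cl,
)

__all__ = [
    "ConcentrationObservation",
    "MAPResult",
    "SamplingPlan",
    "map_estimate",
    "map_objective",
    "recommend_sampling",
]

#: Fixed multi-start points in eta space (besides the prior mode).
_STARTS = ((0.0, 0.0), (0.5, 0.0), (-0.5, 0.0), (0.0, 0.5), (0.0, -0.5))

#: Observations later than this margin after the last infusion ends are
#: outside the dosing-history span and rejected.
_SPAN_MARGIN_H = 48.0


class ConcentrationObservation(BaseModel):
    """A measured serum level with its exact (possibly off-nominal) time."""

    time: float = Field(ge=0, description="h from first infusion start")
    value: float = Field(gt=0, description="mg/L")
    kind: Literal["trough", "peak", "random"] = "random"


class MAPResult(BaseModel):
    ind: IndividualPK
    objective: float
    n_obs: int
    converged: bool
    auc_report: Optional[AUCReport] = None
    grad_norm: Optional[float] = None


class SamplingPlan(BaseModel):
    two_point: bool
    trough: str
    peak: Optional[str] = None
    tdm_day: int
    citations: list[str] = Field(default_factory=list)


def map_objective(
    eta: np.ndarray,
    model: PopPKModel,
    cl_pop: float,
    times: np.ndarray,
    values: np.ndarray,
    starts: np.ndarray,
    amounts: np.ndarray,
    durations: np.ndarray,
):
    """Penalized weighted least-squares objective; analytic in eta (complex
    inputs propagate, enabling complex-step gradients)."""
    cl = cl_pop * np.exp(eta[0])
    v = model.v_pop * np.exp(eta[1])
    pred = _profile(times, cl, v, starts, amounts, durations)
    var = (model.sigma_prop * pred) ** 2 + model.sigma_add**2
    data_term = np.sum((values - pred) ** 2 / var)
    prior_term = eta[0] ** 2 / model.omega2_cl + eta[1] ** 2 / model.omega2_v
    return data_term + prior_term


def _objective_and_grad(eta, args):
    """Value via real evaluation, gradient via complex step (h = 1e-20)."""
    eta = np.asarray(eta, dtype=float)
    f = float(np.real(map_objective(eta, *args)))
    h = 1e-20
    grad = np.empty(2)
    for j in range(2):
        e = eta.astype(complex)
        e[j] += 1j * h
        grad[j] = np.imag(map_objective(e, *args)) / h
    return f, grad


def map_estimate(
    model: PopPKModel,
    patient: PatientCovariates,
    doses: DosingHistory,
    obs: Sequence[ConcentrationObservation],
    regimen: Optional[Regimen] = None,
) -> MAPResult:
    """Posterior-mode individual PK estimate.

    Raises ``ValueError`` for an observation outside the dosing-history span
    (before the first infusion or more than 48 h after the last one ends).
    Non-convergence of every optimizer start is flagged on the result, never
    silent.
    """
    clcr = clcr_estimate(patient)
    cl_pop = population_cl(model, clcr)

    if not obs:
        ind = IndividualPK.from_population(model, clcr)
        return MAPResult(
            ind=ind,
            objective=0.0,
            n_obs=0,
            converged=True,
            auc_report=auc_report(ind, doses, regimen) if doses.events else None,
        )

    if model.omega2_cl <= 0 or model.omega2_v <= 0:
        raise ValueError("between-subject variances must be > 0 to fit observations")

    t0, t_end = doses.span
    for o in obs:
        if o.time < t0 or o.time > t_end + _SPAN_MARGIN_H:
            raise ValueError(
                f"observation at t={o.time} h lies outside the dosing history span "
                f"[{t0}, {t_end + _SPAN_MARGIN_H}] h"
            )

    times = np.array([o.time for o in obs])
    values = np.array([o.value for o in obs])
    starts, amounts, durations = doses.arrays()
    args = (model, cl_pop, times, values, starts, amounts, durations)

    best = None
    any_converged = False
    for start in _STARTS:
        res = minimize(
            lambda e: _objective_and_grad(e, args),
            np.array(start),
            jac=True,
            method="L-BFGS-B",
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        key = (res.fun, float(np.linalg.norm(res.x)))  # tie-break: smallest ||eta||
        if best is None or key < best[0]:
            best = (key, res)
    assert best is not None
    res = best[1]
    _, grad = _objective_and_grad(res.x, args)
    ind = IndividualPK.from_population(
        model, clcr, eta_cl=float(res.x[0]), eta_v=float(res.x[1])
    )
    return MAPResult(
        ind=ind,
        objective=float(res.fun),
        n_obs=len(obs),
        converged=any_converged,
        auc_report=auc_report(ind, doses, regimen),
        grad_norm=float(np.linalg.norm(grad)),
    )


def recommend_sampling(patient: PatientCovariates, regimen: Regimen) -> SamplingPlan:
    """Two-point (trough + peak 1-2 h after the end of infusion) vs
    trough-only sampling.

    Two-point measurement is recommended for once-daily (q24h) schedules,
    patients at high AKI risk, and serious/complicated infections;
    trough-only is admissible for mild infections on a q12h schedule.
    Augmented-clearance (q8h) schedules default to two-point sampling.
    """
    from .guideline import aki_risk

    risk = aki_risk(patient)
    citations = []
    two_point = True
    if regimen.interval >= 24.0:
        citations.append("CQ4(1)")
    elif risk.level == "high":
        citations.append("CQ4(1)")
    elif patient.flags.serious_infection:
        citations.append("CQ4(1)")
    elif regimen.interval == 12.0:
        two_point = False
        citations.append("CQ4(3)")
    else:
        citations.append("CQ4(1)")

    day = _tdm_day(patient, regimen)
    peak_desc = "1-2 h after the end of infusion"
    return SamplingPlan(
        two_point=two_point,
        trough="immediately before the next dose (record the exact time)",
        peak=peak_desc if two_point else None,
        tdm_day=day,
        citations=citations,
    )


def _tdm_day(patient: PatientCovariates, regimen: Regimen) -> int:
    """Day of first TDM: 2 for serious infection / high AKI risk / q24h /
    ICU, else 3 (near steady state)."""
    from .guideline import aki_risk

    early = (
        patient.flags.serious_infection
        or patient.flags.icu
        or aki_risk(patient).level == "high"
        or regimen.interval >= 24.0
    )
    return 2 if early else 3
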