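"""Virtual patients and simulated TDM observations.

Covariates emulate the adult Japanese population behind the packaged prior:
age 19.3-89.6 (mean 64.3) years, actual body weight 25.5-75.0 (52.3) kg, and
measured creatinine clearance 6.85-85.0 (mean 77.1) mL/min.  Each covariate
is drawn from a truncated normal whose location is solved so the *truncated*
mean matches the printed mean (the printed CLcr mean of 77.1 sits close to
the upper bound 85, which the solver accommodates with a location above the
bound; the distribution is strongly left-skewed as a result — encoded as
printed).

Sampling-time scatter reproduces the recorded real-world distribution of
"trough" draws: for q12h dosing the time after the previous dose falls in
bins <10 h (5.9%), 10-11 (22.8%), 11-12 (55.0%), >=12 h (16.3%); for q24h,
<22 (24.1%), 22-23 (27.6%), 23-24 (41.4%), >24 h (6.9%).  Within a bin the
time is uniform; the open outer bins are given 2 h (inner edge) and 1 h
(outer edge) widths.

Measurement noise is proportional + additive on the model prediction, the
same residual structure the MAP objective assumes.  CLcr is sampled directly
(as a measured clearance) rather than through an invented creatinine
distribution.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .bayes import ConcentrationObservation
from .pkmodel import (
    DosingHistory,
    IndividualPK,
    PatientCovariates,
    PopPKModel,
    Regimen,
    RiskFlags,
    concentration,
)

__all__ = [
    "PopulationSpec",
    "sample_patients",
    "sample_individual",
    "simulate_observations",
    "write_fixture",
]

# q12h trough-time bins: (low, high, probability); outer bins bounded for
# uniform draws.
_Q12_BINS = ((8.0, 10.0, 0.059), (10.0, 11.0, 0.228), (11.0, 12.0, 0.550),
             (12.0, 13.0, 0.163))
_Q24_BINS = ((20.0, 22.0, 0.241), (22.0, 23.0, 0.276), (23.0, 24.0, 0.414),
             (24.0, 25.0, 0.069))


class PopulationSpec(BaseModel):
    """Ranges and means of the development population plus flag prevalences
    (prevalences are package defaults, not published values)."""

    age_range: tuple[float, float] = (19.3, 89.6)
    age_mean: float = 64.3
    weight_range: tuple[float, float] = (25.5, 75.0)
    weight_mean: float = 52.3
    clcr_range: tuple[float, float] = (6.85, 85.0)
    clcr_mean: float = 77.1
    female_fraction: float = 0.5
    flag_prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "icu": 0.20,
            "piperacillin_tazobactam": 0.15,
            "diuretics": 0.20,
            "other_nephrotoxins": 0.10,
            "serious_infection": 0.30,
        }
    )

    def trough_bins(self, interval: float):
        return _Q24_BINS if interval >= 24.0 else _Q12_BINS


def _truncnorm_matched(lo: float, hi: float, target_mean: float, sd: float):
    """Truncated normal on [lo, hi] whose mean equals ``target_mean``.

    The location is solved by root finding; sd defaults to range/4 at the
    call sites so ~95% of the untruncated mass sits inside the range for a
    centred mean.
    """

    def mean_err(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    span = hi - lo
    loc = brentq(mean_err, lo - 5 * span, hi + 5 * span, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm(a, b, loc=loc, scale=sd)


def sample_patients(
    spec: Optional[PopulationSpec] = None,
    n: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[PatientCovariates]:
    """Draw ``n`` virtual patients; reproducible under a fixed seed."""
    spec = spec or PopulationSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return []
    dists = {
        "age": _truncnorm_matched(*spec.age_range, spec.age_mean,
                                  (spec.age_range[1] - spec.age_range[0]) / 4),
        "weight": _truncnorm_matched(*spec.weight_range, spec.weight_mean,
                                     (spec.weight_range[1] - spec.weight_range[0]) / 4),
        "clcr": _truncnorm_matched(*spec.clcr_range, spec.clcr_mean,
                                   (spec.clcr_range[1] - spec.clcr_range[0]) / 4),
    }
    ages = dists["age"].rvs(n, random_state=rng)
    weights = dists["weight"].rvs(n, random_state=rng)
    clcrs = dists["clcr"].rvs(n, random_state=rng)
    females = rng.random(n) < spec.female_fraction
    flag_names = list(spec.flag_prevalence)
    flag_draws = {
        name: rng.random(n) < p for name, p in spec.flag_prevalence.items()
    }
    patients = []
    for i in range(n):
        patients.append(
            PatientCovariates(
                age=float(ages[i]),
                weight=float(weights[i]),
                sex="female" if females[i] else "male",
                clcr_measured=float(clcrs[i]),
                flags=RiskFlags(**{name: bool(flag_draws[name][i]) for name in flag_names}),
            )
        )
    return patients


def sample_individual(
    model: PopPKModel,
    clcr: float,
    rng: np.random.Generator,
) -> IndividualPK:
    """Draw individual PK parameters from the log-normal prior."""
    eta_cl = rng.normal(0.0, np.sqrt(model.omega2_cl))
    eta_v = rng.normal(0.0, np.sqrt(model.omega2_v))
    return IndividualPK.from_population(model, clcr, eta_cl=eta_cl, eta_v=eta_v)


def _jitter_trough_time(
    nominal_dose_time: float,
    prev_dose_time: float,
    interval: float,
    spec: PopulationSpec,
    rng: np.random.Generator,
) -> float:
    bins = spec.trough_bins(interval)
    probs = np.array([b[2] for b in bins])
    idx = rng.choice(len(bins), p=probs / probs.sum())
    lo, hi, _ = bins[idx]
    return prev_dose_time + rng.uniform(lo, hi)


def simulate_observations(
    ind: IndividualPK,
    doses: DosingHistory,
    spec: Optional[PopulationSpec] = None,
    seed: int | np.random.Generator = 0,
    sigma_prop: float = 0.10,
    sigma_add: float = 0.5,
    trough_dose_index: int = 2,
    include_peak: bool = True,
    jitter: bool = True,
) -> tuple[list[ConcentrationObservation], dict]:
    """Simulate a TDM draw around the dose at ``trough_dose_index``.

    The trough is nominally immediately before that dose and, when
    ``jitter`` is on, displaced per the recorded sampling-time scatter; the
    peak (if requested) is drawn 1-2 h after the end of that dose's
    infusion.  Returns the observations plus a truth record (exact times,
    noise-free concentrations, parameters) for recovery tests.
    """
    spec = spec or PopulationSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = doses.events
    if trough_dose_index >= len(events):
        raise ValueError("trough_dose_index beyond dosing history")
    dose_ev = events[trough_dose_index]
    prev_ev = events[trough_dose_index - 1]
    interval = dose_ev.start_time - prev_ev.start_time

    if jitter:
        t_trough = _jitter_trough_time(
            dose_ev.start_time, prev_ev.start_time, interval, spec, rng
        )
    else:
        t_trough = dose_ev.start_time - 1e-9
    samples = [("trough", t_trough)]
    if include_peak:
        t_peak = dose_ev.end_time + (rng.uniform(1.0, 2.0) if jitter else 1.0)
        samples.append(("peak", t_peak))

    observations = []
    truth = {"cl": ind.cl, "v": ind.v, "eta_cl": ind.eta_cl, "eta_v": ind.eta_v,
             "samples": []}
    for kind, t in samples:
        c_true = float(concentration(ind, doses, t))
        noisy = c_true * (1.0 + sigma_prop * rng.standard_normal()) + (
            sigma_add * rng.standard_normal()
        )
        noisy = max(noisy, 0.05)  # assay floor keeps values positive
        observations.append(ConcentrationObservation(time=t, value=noisy, kind=kind))
        truth["samples"].append({"kind": kind, "time": t, "conc_true": c_true})
    return observations, truth


def write_fixture(
    directory: str | Path,
    patients: Sequence[PatientCovariates],
    histories: Sequence[DosingHistory],
    observations: Sequence[Sequence[ConcentrationObservation]],
    seed: int,
    spec: Optional[PopulationSpec] = None,
) -> None:
    """Emit patient/dosing/observation CSVs plus a manifest JSON."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": i,
                "age_y": p.age,
                "weight_kg": p.weight,
                "sex": p.sex,
                "clcr_ml_min": p.clcr_measured,
                **{f"flag_{k}": v for k, v in p.flags.model_dump().items()},
            }
            for i, p in enumerate(patients)
        ]
    ).to_csv(directory / "patients.csv", index=False)
    pd.DataFrame(
        [
            {"patient_id": i, "time_h": e.start_time, "dose_mg": e.amount,
             "duration_h": e.duration}
            for i, h in enumerate(histories)
            for e in h.events
        ]
    ).to_csv(directory / "doses.csv", index=False)
    pd.DataFrame(
        [
            {"patient_id": i, "time_h": o.time, "conc_mg_L": o.value, "kind": o.kind}
            for i, obs in enumerate(observations)
            for o in obs
        ]
    ).to_csv(directory / "observations.csv", index=False)
    manifest = {
        "seed": seed,
        "n_patients": len(patients),
        "population_spec": (spec or PopulationSpec()).model_dump(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
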