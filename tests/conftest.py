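"""Shared fixtures and independent numerical oracles.

The ODE oracle integrates the one-compartment mass balance
dA/dt = in(t) - k A numerically, piecewise between infusion breakpoints so
the integrator never steps across a rate discontinuity.  It shares no code
with the closed-form superposition solution it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from vancotdm import (
    DoseEvent,
    DosingHistory,
    IndividualPK,
    PatientCovariates,
    PopPKModel,
    default_model,
)


@pytest.fixture(scope="session")
def model() -> PopPKModel:
    return default_model()


@pytest.fixture()
def patient() -> PatientCovariates:
    return PatientCovariates(age=65, weight=60, sex="male", clcr_measured=80)


def ode_concentration(
    ind: IndividualPK, doses: DosingHistory, times: np.ndarray
) -> np.ndarray:
    """Concentration by stiff-safe numerical integration of the mass balance."""
    k = ind.cl / ind.v
    events = doses.events
    breaks = sorted({0.0, *(e.start_time for e in events), *(e.end_time for e in events),
                     float(np.max(times))})

    def rate_in(t: float) -> float:
        return sum(e.rate for e in events if e.start_time <= t < e.end_time)

    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    a = 0.0
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi <= lo:
            continue
        r = rate_in((lo + hi) / 2.0)
        sel = (times > lo) & (times <= hi)
        sol = solve_ivp(
            lambda t, y: [r - k * y[0]],
            (lo, hi),
            [a],
            method="LSODA",
            rtol=1e-11,
            atol=1e-12,
            dense_output=True,
        )
        if np.any(sel):
            out[sel] = sol.sol(times[sel])[0]
        a = float(sol.y[0, -1])
    out[times <= breaks[0]] = 0.0
    return out / ind.v


def quad_auc(ind: IndividualPK, doses: DosingHistory, t1: float, t2: float) -> float:
    """AUC by adaptive quadrature of the closed-form concentration, split at
    infusion breakpoints (independent of the mass-balance shortcut)."""
    from vancotdm import concentration

    breaks = sorted(
        {t1, t2}
        | {e.start_time for e in doses.events if t1 < e.start_time < t2}
        | {e.end_time for e in doses.events if t1 < e.end_time < t2}
    )
    total = 0.0
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        val, _ = quad(lambda t: float(concentration(ind, doses, t)), lo, hi,
                      limit=200, epsabs=1e-10, epsrel=1e-10)
        total += val
    return total


def random_history(rng: np.random.Generator, n_max: int = 6) -> DosingHistory:
    """A random multi-infusion history for property tests."""
    n = int(rng.integers(1, n_max + 1))
    starts = np.sort(rng.uniform(0.0, 60.0, n))
    starts[0] = 0.0
    return DosingHistory(
        events=[
            DoseEvent(
                start_time=float(s),
                amount=float(rng.uniform(250.0, 2500.0)),
                duration=float(rng.uniform(0.5, 3.0)),
            )
            for s in starts
        ]
    )


def random_individual(rng: np.random.Generator) -> IndividualPK:
    return IndividualPK(
        cl=float(rng.uniform(1.0, 7.0)), v=float(rng.uniform(40.0, 90.0))
    )
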