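"""Structural model, covariate relations and the closed-form simulator."""

import numpy as np
import pytest

from vancotdm import (
    DoseEvent,
    DosingHistory,
    IndividualPK,
    PatientCovariates,
    PopPKModel,
    Regimen,
    RenalFunctionUnavailableError,
    amount_in_body,
    clcr_estimate,
    concentration,
    population_cl,
)

from conftest import ode_concentration, random_history, random_individual


class TestClcrEstimate:
    @pytest.mark.parametrize(
        "sex,expected",
        [("male", (140 - 40) * 70 / (72 * 1.0)), ("female", 0.85 * (140 - 40) * 70 / 72)],
    )
    def test_cockcroft_gault(self, sex, expected):
        p = PatientCovariates(age=40, weight=70, sex=sex, serum_creatinine=1.0)
        assert clcr_estimate(p) == pytest.approx(expected)

    def test_measured_value_passes_through(self):
        p = PatientCovariates(age=40, weight=70, sex="male", serum_creatinine=1.0,
                              clcr_measured=50.0)
        assert clcr_estimate(p) == 50.0

    def test_missing_renal_data_raises(self):
        p = PatientCovariates(age=40, weight=70, sex="male")
        with pytest.raises(RenalFunctionUnavailableError, match="renal function"):
            clcr_estimate(p)


class TestPopulationCl:
    def test_linear_map(self):
        m = PopPKModel(theta_cl_slope=0.05)
        assert population_cl(m, 100.0) == pytest.approx(5.0)

    def test_clcr_cap(self):
        m = PopPKModel(theta_cl_slope=0.05, clcr_cap=130.0)
        assert population_cl(m, 200.0) == population_cl(m, 130.0)

    def test_nonpositive_result_is_configuration_error(self):
        m = PopPKModel(theta_cl_slope=0.01, theta_cl_intercept=-5.0)
        with pytest.raises(ValueError, match="non-positive clearance"):
            population_cl(m, 50.0)


class TestConcentration:
    def setup_method(self):
        self.ind = IndividualPK(cl=4.88, v=60.7)
        self.hist = DosingHistory(
            events=[DoseEvent(start_time=0.0, amount=1000.0, duration=1.0)]
        )

    def test_zero_before_anything_infused(self):
        assert concentration(self.ind, self.hist, 0.0) == 0.0

    def test_end_of_infusion_closed_form(self):
        # (R0/CL)(1 - e^{-k t}) at t = 1 h
        k = 4.88 / 60.7
        expected = (1000.0 / 4.88) * (1.0 - np.exp(-k))
        assert concentration(self.ind, self.hist, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(15.8, abs=0.05)

    def test_dose_linearity(self):
        t = np.linspace(0, 24, 97)
        doubled = DosingHistory(
            events=[DoseEvent(start_time=0.0, amount=2000.0, duration=1.0)]
        )
        np.testing.assert_allclose(
            concentration(self.ind, doubled, t),
            2.0 * concentration(self.ind, self.hist, t),
            rtol=1e-12,
        )

    def test_superposition_of_single_doses(self):
        rng = np.random.default_rng(7)
        hist = random_history(rng)
        t = np.linspace(0.0, 80.0, 321)
        total = concentration(self.ind, hist, t)
        summed = sum(
            concentration(self.ind, DosingHistory(events=[e]), t)
            for e in hist.events
        )
        np.testing.assert_allclose(total, summed, rtol=1e-13, atol=1e-13)

    def test_positive_and_continuous(self):
        rng = np.random.default_rng(3)
        hist = random_history(rng)
        t = np.linspace(0.0, 90.0, 4001)
        c = concentration(self.ind, hist, t)
        assert np.all(c >= 0)
        # continuity: no jump bigger than the local infusion-rate bound
        max_rate = max(e.rate for e in hist.events) * len(hist.events)
        dt = t[1] - t[0]
        assert np.max(np.abs(np.diff(c))) < (max_rate / self.ind.v + 5.0) * dt


@pytest.mark.parametrize("seed", range(20))
def test_closed_form_matches_ode_oracle(seed):
    """Closed-form superposition vs numerical mass-balance integration on
    random regimens: relative error <= 1e-6 wherever C is non-negligible."""
    rng = np.random.default_rng(1000 + seed)
    ind = random_individual(rng)
    hist = random_history(rng)
    t = np.sort(rng.uniform(0.5, 80.0, 25))
    c_closed = concentration(ind, hist, t)
    c_ode = ode_concentration(ind, hist, t)
    mask = c_ode > 1e-6
    np.testing.assert_allclose(c_closed[mask], c_ode[mask], rtol=1e-6)


def test_amount_in_body_limits_and_oracle():
    ind = IndividualPK(cl=4.0, v=50.0)
    hist = DosingHistory(
        events=[
            DoseEvent(start_time=0.0, amount=1500.0, duration=1.5),
            DoseEvent(start_time=12.0, amount=1000.0, duration=1.0),
        ]
    )
    assert amount_in_body(ind, hist, 0.0) == 0.0
    # washes out: ten half-lives after the last dose
    t_half = np.log(2) / ind.k
    assert amount_in_body(ind, hist, 13.0 + 10 * t_half) < 2500.0 * 2**-9
    t = np.array([1.0, 5.0, 12.5, 20.0])
    np.testing.assert_allclose(
        amount_in_body(ind, hist, t),
        ode_concentration(ind, hist, t) * ind.v,
        rtol=1e-6,
    )


class TestRegimen:
    @pytest.mark.parametrize(
        "name,ld,md",
        [("A-1", None, 900.0), ("A-2", None, 1200.0),
         ("B-1", 1500.0, 900.0), ("B-2", 1800.0, 1200.0)],
    )
    def test_presets_scale_with_weight(self, name, ld, md):
        r = Regimen.from_preset(name, weight=60.0)
        assert r.loading_dose == ld
        assert r.maintenance_dose == md
        assert r.interval == 12.0

    def test_to_history_schedule(self):
        r = Regimen(loading_dose=1800, maintenance_dose=1200, interval=12, n_days=2)
        hist = r.to_history()
        starts = [e.start_time for e in hist.events]
        assert starts == [0.0, 12.0, 24.0, 36.0]
        assert hist.events[0].amount == 1800
        # 30 min / 0.5 g rule: 1800 mg -> 1.8 h, 1200 mg -> 1.2 h
        assert hist.events[0].duration == pytest.approx(1.8)
        assert hist.events[1].duration == pytest.approx(1.2)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            Regimen.from_preset("C-1", weight=60.0)

    def test_events_sorted_on_validation(self):
        h = DosingHistory(
            events=[
                DoseEvent(start_time=12.0, amount=500, duration=1.0),
                DoseEvent(start_time=0.0, amount=500, duration=1.0),
            ]
        )
        assert [e.start_time for e in h.events] == [0.0, 12.0]
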