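"""Plant simulator: dynamics oracles, bolus bookkeeping, sampling."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from gmpc.plant import (
    BolusEvent,
    Measurement,
    PhaseSchedule,
    PlantParams,
    PlantState,
    apply_bolus,
    integrate,
    plant_derivative,
    sample_measurement,
)
from gmpc.errors import ScenarioConfigError
from gmpc.ratemap import GrowthMode


@pytest.fixture
def params():
    return PlantParams()


class TestSchedule:
    def test_default_photoperiod(self):
        s = PhaseSchedule()
        assert s.period == 24.0
        assert s.phase_at(0.0) is GrowthMode.LIGHT
        assert s.phase_at(16.0) is GrowthMode.DARK
        assert s.phase_at(24.0) is GrowthMode.LIGHT
        assert s.phase_at(47.9) is GrowthMode.DARK

    def test_segments_cover_span(self):
        s = PhaseSchedule()
        segs = list(s.segments(0.0, 96.0))
        assert segs[0] == (0.0, 16.0, GrowthMode.LIGHT)
        assert sum(b - a for a, b, _ in segs) == pytest.approx(96.0)
        assert len([1 for *_, m in segs if m is GrowthMode.DARK]) == 4

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ScenarioConfigError):
            PhaseSchedule(blocks=((GrowthMode.LIGHT, -1.0),))
        with pytest.raises(ScenarioConfigError):
            PhaseSchedule(blocks=((GrowthMode.LIGHT, 8.0), (GrowthMode.LIGHT, 8.0)))


class TestDerivative:
    def test_light_limit_is_shading_amplitude(self, params):
        """As biomass -> 0 the light specific growth rate -> 0.0338 1/h."""
        st = PlantState(t=0, x=1e-9, g=0.0, n=100.0, v=2.0)
        dx, dg, dn, dv = plant_derivative(st, params, GrowthMode.LIGHT)
        assert dx / st.x == pytest.approx(0.0338, rel=1e-5)
        assert dg == 0.0
        assert dn < 0 and dv == 0.0

    def test_dark_no_glucose_stops_heterotrophy(self, params):
        st = PlantState(t=0, x=0.2, g=0.0, n=100.0, v=2.0)
        dx, dg, dn, _ = plant_derivative(st, params, GrowthMode.DARK)
        assert dg == 0.0
        assert dx == pytest.approx(0.0, abs=1e-12)  # a_true = 0: no growth at all

    def test_dark_mixotrophic_fraction_adds_growth(self):
        p = PlantParams(a_true=0.5)
        st = PlantState(t=0, x=0.2, g=0.0, n=100.0, v=2.0)
        dx, dg, dn, _ = plant_derivative(st, p, GrowthMode.DARK)
        f_n = 100.0 / (p.k_n + 100.0)
        assert dg == 0.0
        assert dx == pytest.approx(0.5 * p.mu_dark_auto * f_n * st.x, rel=1e-12)
        assert dn < 0  # autotrophic fraction still draws nitrate


class TestBolus:
    @pytest.mark.parametrize(
        "f_g, f_n, exp_tg, exp_tn",
        [(0.0, 75.0, 0.0, 10.0), (150.0, 0.0, 5.0, 0.0)],
    )
    def test_pump_runtimes_match_pump_equation(self, params, f_g, f_n, exp_tg, exp_tn):
        """T_pump = F·V/(C·Q): 75 mg/L nitrate into 2 L -> 10 s, 150 mg/L glucose -> 5 s."""
        st = PlantState(t=0, x=0.1, g=0, n=0, v=2.0)
        e = BolusEvent(time=0.0, f_g=f_g, f_n=f_n)
        apply_bolus(st, e, params)
        assert e.t_pump_g == pytest.approx(exp_tg)
        assert e.t_pump_n == pytest.approx(exp_tn)

    def test_zero_bolus_is_identity(self, params):
        st = PlantState(t=0, x=0.1, g=12.0, n=34.0, v=2.0)
        out = apply_bolus(st, BolusEvent(time=0.0), params)
        assert out == st

    def test_exact_mixing_conserves_mass_and_dilutes_biomass(self, params):
        st = PlantState(t=0, x=0.5, g=10.0, n=5.0, v=2.0)
        e = BolusEvent(time=0.0, f_g=200.0, f_n=100.0)
        out = apply_bolus(st, e, params)
        assert out.v == pytest.approx(2.0 + 0.02 + 0.04)  # 400/20 mL + 200/5 mL
        assert out.g * out.v == pytest.approx(st.g * st.v + 200.0 * 2.0, rel=1e-12)
        assert out.n * out.v == pytest.approx(st.n * st.v + 100.0 * 2.0, rel=1e-12)
        assert out.x * out.v == pytest.approx(st.x * st.v, rel=1e-12)  # cells conserved
        assert out.x < st.x

    def test_no_dilution_toggle(self):
        p = PlantParams(dilution=False)
        st = PlantState(t=0, x=0.5, g=10.0, n=5.0, v=2.0)
        out = apply_bolus(st, BolusEvent(time=0.0, f_g=200.0), p)
        assert out.v == st.v
        assert out.g == pytest.approx(210.0)


class TestIntegrate:
    def test_dark_exponential_matches_closed_form(self):
        """Abundant substrate, Monod constants -> 0: pure exponential growth."""
        p = PlantParams(k_g=1e-9, k_n=1e-9)
        st = PlantState(t=0, x=0.1, g=2000.0, n=500.0, v=2.0)
        traj = integrate(st, PhaseSchedule.constant(GrowthMode.DARK), [], 8.0, p)
        assert traj.final_state().x == pytest.approx(0.1 * math.exp(0.023 * 8), rel=1e-6)

    def test_light_no_shading_matches_closed_form(self):
        p = PlantParams(k_shading=0.0)
        st = PlantState(t=0, x=0.05, g=0.0, n=500.0, v=2.0)
        traj = integrate(st, PhaseSchedule.constant(GrowthMode.LIGHT), [], 16.0, p)
        assert traj.final_state().x == pytest.approx(0.05 * math.exp(0.0338 * 16), rel=1e-6)

    def test_light_shading_matches_quadrature_oracle(self, params):
        """Independent 1-D quadrature: time to reach x_end must equal 16 h.

        Separating dx/(mu0 e^{-k·1000x} x) = dt gives the travel time as an
        integral evaluated by adaptive quadrature, with no ODE solver involved.
        """
        x0 = 0.035  # 35 mg/L
        st = PlantState(t=0, x=x0, g=0.0, n=1e6, v=2.0)  # N effectively unlimited
        traj = integrate(st, PhaseSchedule.constant(GrowthMode.LIGHT), [], 16.0, params)
        x_end = traj.final_state().x
        t_travel, err = quad(
            lambda x: 1.0 / (0.0338 * math.exp(-0.00174 * 1000.0 * x) * x),
            x0, x_end, epsabs=1e-12, epsrel=1e-12,
        )
        # the Monod nitrate factor at N=1e6 is 1 - 2e-6; allow for it
        assert t_travel == pytest.approx(16.0, rel=1e-5)

    def test_substrate_exhaustion_stays_nonnegative(self, params):
        st = PlantState(t=0, x=0.3, g=15.0, n=100.0, v=2.0)
        traj = integrate(st, PhaseSchedule.constant(GrowthMode.DARK), [], 8.0, params)
        assert (traj.frame["G"] >= 0).all()
        assert traj.final_state().g < 1.0  # consumed to near zero
        # growth decelerates: final specific rate well below the start
        x = traj.frame["x"].to_numpy()
        t = traj.frame["t"].to_numpy()
        mu_start = (x[1] - x[0]) / (x[0] * (t[1] - t[0]))
        mu_end = (x[-1] - x[-2]) / (x[-2] * (t[-1] - t[-2]))
        assert mu_end < 0.2 * mu_start

    def test_mass_balance_with_boluses(self, params):
        st = PlantState(t=0, x=0.1, g=50.0, n=50.0, v=2.0)
        events = [BolusEvent(time=8.0, f_g=120.0, f_n=40.0),
                  BolusEvent(time=16.0, f_g=90.0, f_n=30.0)]
        traj = integrate(st, PhaseSchedule.constant(GrowthMode.DARK), events, 24.0, params)
        fed_g = sum(e.f_g * (traj.state_at(e.time).v - e.added_volume) for e in traj.events)
        cons_g, _ = traj.consumed()
        final = traj.final_state()
        lhs = st.g * st.v + fed_g - cons_g
        assert lhs == pytest.approx(final.g * final.v, rel=1e-6, abs=1e-6)

    def test_dark_monotonic_depletion_light_constant_glucose(self, params):
        st = PlantState(t=0, x=0.2, g=100.0, n=100.0, v=2.0)
        traj = integrate(st, PhaseSchedule(), [], 24.0, params)
        light = traj.frame[traj.frame["phase"] == "light"]
        dark = traj.frame[traj.frame["phase"] == "dark"]
        assert light["G"].nunique() == 1  # no glucose uptake in the light
        assert (np.diff(dark["G"].to_numpy()) <= 1e-9).all()
        assert (np.diff(dark["N"].to_numpy()) <= 1e-9).all()

    def test_sample_times_strictly_increasing(self, params):
        st = PlantState(t=0, x=0.1, g=50.0, n=50.0, v=2.0)
        traj = integrate(st, PhaseSchedule(), [BolusEvent(time=16.0, f_g=10.0)], 30.0, params)
        assert (np.diff(traj.frame["t"].to_numpy()) > 0).all()


class TestMeasurement:
    @pytest.fixture
    def traj(self, params):
        st = PlantState(t=0, x=0.1, g=50.0, n=50.0, v=2.0)
        return integrate(st, PhaseSchedule.constant(GrowthMode.DARK), [], 8.0, params)

    def test_noiseless_equals_truth(self, traj):
        p0 = PlantParams(sigma_x=0.0, sigma_g=0.0, sigma_n=0.0)
        m = sample_measurement(traj, 4.0, 123, p0)
        st = traj.state_at(4.0)
        assert m.x_m == pytest.approx(st.x * 1000.0)
        assert m.g_m == pytest.approx(st.g)
        assert m.n_m == pytest.approx(st.n)

    def test_seed_determinism(self, traj, params):
        m1 = sample_measurement(traj, 4.0, 99, params)
        m2 = sample_measurement(traj, 4.0, 99, params)
        assert m1 == m2

    def test_noise_sd_calibrated(self, traj):
        p = PlantParams(sigma_x=0.0, sigma_g=2.0, sigma_n=0.0)
        rng = np.random.default_rng(0)
        vals = [sample_measurement(traj, 2.0, rng, p).g_m for _ in range(10_000)]
        assert np.std(vals) == pytest.approx(2.0, rel=0.05)

    def test_out_of_span_rejected(self, traj, params):
        with pytest.raises(ValueError):
            sample_measurement(traj, 99.0, 0, params)

    def test_negative_measurement_rejected(self):
        with pytest.raises(ValueError):
            Measurement(t=0.0, x_m=-1.0, g_m=0.0, n_m=0.0)
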