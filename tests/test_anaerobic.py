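"""Alactic power models, O2-deficit, EPOC measures, and store trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ergokinetics import (
    EnergeticsParameters,
    alactic_energy_model1,
    alactic_energy_model2,
    alactic_power_model1,
    alactic_power_model2,
    bout_with_recovery_profile,
    constant_bout_profile,
    continuous_profile,
    epoc_measures,
    integrate_aerobic,
    integrate_lactate,
    interval_profile,
    metabolic_power_model1,
    oxygen_deficit,
    run_simulation,
)
from ergokinetics.anaerobic import gap_cumtrapz
from ergokinetics import (
    steady_state_concentration,
    work_heat_decomposition,
)


@pytest.fixture(scope="module")
def recovery_run(params, lpar):
    """Subcritical bout + long recovery, warm-started at the recovery state
    so that exercise + recovery forms a closed cycle (Qa and C return to
    their initial values)."""
    q_rec = 0.47 * params.Qmax
    c_rec = steady_state_concentration(q_rec, lpar, params.Qmax)
    prof = bout_with_recovery_profile(0.87, 800.0, 0.47, 1200.0, Qmax=params.Qmax)
    aer = integrate_aerobic(prof, params, dt=0.05, Qvir0=q_rec)
    lac = integrate_lactate(aer, lpar, C0=c_rec)
    return aer, lac


class TestWorkHeatDecomposition:
    def test_aerobic_only_split(self, params):
        s = work_heat_decomposition(100.0, 0.0, 0.0, params)
        assert s.Pa == pytest.approx(30.0)  # eta*eta_a = 0.3
        assert s.Haw == pytest.approx(70.0)
        assert (s.PG, s.PCK) == (0.0, 0.0)
        assert s.PT == s.Pa and s.H == s.Haw

    def test_all_zero(self, params):
        s = work_heat_decomposition(0.0, 0.0, 0.0, params)
        assert s.PT == 0.0 and s.H == 0.0

    @given(
        qaw=st.floats(min_value=0, max_value=2000),
        qg=st.floats(min_value=-500, max_value=500),
        qck=st.floats(min_value=-500, max_value=1500),
    )
    def test_work_plus_heat_recovers_source_powers(self, qaw, qg, qck):
        params = EnergeticsParameters()
        s = work_heat_decomposition(qaw, qg, qck, params)
        assert s.PT + s.H == pytest.approx(qaw + qg + qck, rel=1e-12, abs=1e-9)


class TestModel1Powers:
    def test_zero_at_steady_state(self, params):
        q = 0.8 * params.Qmax
        assert alactic_power_model1(q, q, 0.0, params) == 0.0

    def test_onset_from_rest(self, params):
        got = alactic_power_model1(1640.8, 80.0, 0.0, params)
        assert got == pytest.approx(0.6 / 0.95 * 1560.8, rel=1e-12)
        assert got == pytest.approx(985.8, abs=0.1)

    def test_negative_lactic_power_boosts_recharge(self, params):
        base = alactic_power_model1(900.0, 1000.0, 0.0, params)
        with_removal = alactic_power_model1(900.0, 1000.0, -50.0, params)
        assert with_removal > base  # PCr rebuilt partly at glycolytic expense

    @given(
        qa=st.floats(min_value=80, max_value=1886),
        qg=st.floats(min_value=-500, max_value=500),
        qbar=st.floats(min_value=80, max_value=2100),
    )
    def test_power_balance_identity(self, qa, qg, qbar):
        """Q1 == Qr + (Qa-Qr) + QG + QCK1 for arbitrary states."""
        params = EnergeticsParameters()
        q1 = metabolic_power_model1(qa, qg, qbar, params)
        rebuilt = (
            params.Qr
            + (qa - params.Qr)
            + qg
            + alactic_power_model1(qbar, qa, qg, params)
        )
        assert q1 == pytest.approx(rebuilt, rel=1e-9, abs=1e-9)

    def test_reduces_to_qa_at_steady_state(self, params):
        q = 0.7 * params.Qmax
        assert metabolic_power_model1(q, 0.0, q, params) == pytest.approx(q, rel=1e-12)


class TestModel2Power:
    def test_zero_at_steady_state(self):
        assert alactic_power_model2(0.0, 20.0) == 0.0

    def test_onset_from_rest(self):
        assert alactic_power_model2(52.027, 20.0) == pytest.approx(1040.5, abs=0.1)

    def test_negative_during_recovery(self):
        assert alactic_power_model2(-10.0, 20.0) < 0


class TestOxygenDeficit:
    def test_zero_at_steady_state(self, params, lpar):
        prof = constant_bout_profile(params.Qr / params.Qmax, 100.0, Qmax=params.Qmax)
        aer = integrate_aerobic(prof, params, dt=0.1)
        assert oxygen_deficit(aer, 0.0, 100.0) == pytest.approx(0.0, abs=1e-9)

    def test_long_bout_deficit_approaches_tau_a_times_gap(self, params):
        prof = constant_bout_profile(0.8, 600.0, Qmax=params.Qmax)
        aer = integrate_aerobic(prof, params, dt=0.05)
        expected = params.tau_a * (0.8 * params.Qmax - params.Qr)
        assert oxygen_deficit(aer, 0.0, 600.0) == pytest.approx(expected, rel=1e-5)

    def test_references_differ_only_when_supramaximal(self, params):
        sub = integrate_aerobic(
            constant_bout_profile(0.8, 200.0, Qmax=params.Qmax), params, dt=0.1
        )
        assert oxygen_deficit(sub, 0, 200) == pytest.approx(
            oxygen_deficit(sub, 0, 200, reference="Qbar_a"), rel=1e-12
        )
        supra = integrate_aerobic(
            constant_bout_profile(1.09, 200.0, Qmax=params.Qmax), params, dt=0.1
        )
        assert oxygen_deficit(supra, 0, 200) > oxygen_deficit(
            supra, 0, 200, reference="Qbar_a"
        )


class TestEnergies:
    def test_model1_energy_matches_power_quadrature(self, params, lpar):
        prof = bout_with_recovery_profile(0.8, 400.0, 0.47, 200.0, Qmax=params.Qmax)
        aer = integrate_aerobic(prof, params, dt=0.05)
        lac = integrate_lactate(aer, lpar)
        qg = params.m * params.lambda_ * lac.Cdot
        qck1_right = np.array(
            [
                alactic_power_model1(qb, qa, g, params)
                for qb, qa, g in zip(aer.Qbar_vir, aer.Qa, qg)
            ]
        )
        qck1_left = np.array(
            [
                alactic_power_model1(qb, qa, g, params)
                for qb, qa, g in zip(aer.Qbar_vir_pre, aer.Qa, qg)
            ]
        )
        # one-sided limits at the work->recovery jump so no trapezoid
        # straddles the discontinuity in Qbar_vir
        quad = gap_cumtrapz(aer.t, qck1_right, qck1_left)[-1]
        closed = alactic_energy_model1(aer, lac, 0.0, 600.0, params)
        assert quad == pytest.approx(closed, rel=1e-6)

    def test_model2_energy_closed_form_and_area_rule(self, params):
        prof = constant_bout_profile(0.8, 300.0, Qmax=params.Qmax)
        aer = integrate_aerobic(prof, params, dt=0.05)
        closed = alactic_energy_model2(aer, 0.0, 300.0, params.theta)
        assert closed == pytest.approx(
            params.theta * (aer.Qa[-1] - aer.Qa[0]), rel=1e-12
        )
        # subcritical: (theta/tau_a) x area between Qbar_a and Qa
        area = oxygen_deficit(aer, 0.0, 300.0, reference="Qbar_a")
        assert params.theta / params.tau_a * area == pytest.approx(closed, rel=1e-6)

    def test_model2_path_independence_across_dt(self, params):
        prof = bout_with_recovery_profile(0.9, 300.0, 0.5, 300.0, Qmax=params.Qmax)
        vals = []
        for dt in (0.2, 0.1, 0.05):
            aer = integrate_aerobic(prof, params, dt=dt)
            vals.append(alactic_energy_model2(aer, 0.0, 600.0, params.theta))
        assert vals[0] == pytest.approx(vals[2], rel=1e-8)
        assert vals[1] == pytest.approx(vals[2], rel=1e-8)

    def test_deficit_equals_anaerobic_energy_when_efficiencies_equal(self, lpar):
        params = EnergeticsParameters(eta_CK=0.6)  # eta_G = eta_CK = eta_a
        prof = constant_bout_profile(0.8, 400.0, Qmax=params.Qmax)
        aer = integrate_aerobic(prof, params, dt=0.1)
        lac = integrate_lactate(aer, lpar)
        eck1 = alactic_energy_model1(aer, lac, 0.0, 400.0, params)
        eg = params.m * params.lambda_ * (lac.C[-1] - lac.C[0])
        ean1 = eck1 + eg
        assert ean1 == pytest.approx(oxygen_deficit(aer, 0.0, 400.0), rel=1e-9)


class TestClosedCycle:
    def test_lactic_and_model2_energies_vanish(self, recovery_run, params):
        aer, lac = recovery_run
        t2 = aer.t[-1]
        eg_cycle = params.m * params.lambda_ * (lac.C[-1] - lac.C[0])
        eg_bout = params.m * params.lambda_ * (lac.C[lac.index_of(800.0)] - lac.C[0])
        assert abs(eg_cycle) < 1e-6 * abs(eg_bout)
        eck2_cycle = alactic_energy_model2(aer, 0.0, t2, params.theta)
        eck2_bout = alactic_energy_model2(aer, 0.0, 800.0, params.theta)
        assert abs(eck2_cycle) < 1e-6 * abs(eck2_bout)

    def test_model1_recovery_decomposition(self, recovery_run, params):
        """E_CK1 over the bout equals the energy-depth + lactic-recovery split."""
        aer, lac = recovery_run
        t1, t2 = 800.0, aer.t[-1]
        lhs = alactic_energy_model1(aer, lac, 0.0, t1, params)
        edb, _, _ = epoc_measures(aer, t1, t2)
        eg_rec = params.m * params.lambda_ * (lac.C[lac.index_of(t2)] - lac.C[lac.index_of(t1)])
        rhs = params.eta_a / params.eta_CK * edb + params.eta_G / params.eta_CK * eg_rec
        scale = params.eta_a / params.eta_CK * abs(edb)
        assert abs(lhs - rhs) < 1e-5 * scale

    def test_model2_bout_equals_minus_recovery(self, recovery_run, params):
        aer, _ = recovery_run
        bout = alactic_energy_model2(aer, 0.0, 800.0, params.theta)
        rec = alactic_energy_model2(aer, 800.0, aer.t[-1], params.theta)
        assert bout == pytest.approx(-rec, rel=1e-9)


class TestEpocMeasures:
    def test_constant_qa_gives_zero_epoc_alt(self, params):
        prof = constant_bout_profile(params.Qr / params.Qmax, 100.0, Qmax=params.Qmax)
        aer = integrate_aerobic(prof, params, dt=0.1)
        _, _, epoc_alt = epoc_measures(aer, 0.0, 100.0)
        assert epoc_alt == 0.0

    def test_three_measures_agree_on_subcritical_recovery(self, recovery_run, params):
        aer, _ = recovery_run
        edb, epoc, epoc_alt = epoc_measures(aer, 800.0, aer.t[-1])
        assert epoc_alt > 0
        assert edb == pytest.approx(epoc_alt, rel=1e-6)
        assert epoc == pytest.approx(epoc_alt, rel=1e-6)

    def test_anaerobic_energy_epoc_identity(self, recovery_run, lpar):
        """Total anaerobic energy of the bout from recovery measurements alone,
        with theta derived from the efficiency ratio."""
        params = EnergeticsParameters().with_derived_theta()
        aer, lac = recovery_run
        t1, t2 = 800.0, aer.t[-1]
        edf = oxygen_deficit(aer, 0.0, t1)
        m, lam = params.m, params.lambda_
        eg_bout = m * lam * (lac.C[lac.index_of(t1)] - lac.C[0])
        ean1 = params.eta_a / params.eta_CK * edf + (1 - params.eta_G / params.eta_a) * eg_bout
        _, epoc, _ = epoc_measures(aer, t1, t2)
        eg_rec = m * lam * (lac.C[lac.index_of(t2)] - lac.C[lac.index_of(t1)])
        rhs = params.theta / params.tau_a * epoc + (params.eta_G / params.eta_a - 1) * eg_rec
        assert ean1 == pytest.approx(rhs, rel=1e-4)


class TestStoreTrajectories:
    def test_fractions_start_at_one(self, params, lpar):
        res = run_simulation(
            constant_bout_profile(0.8, 300.0, Qmax=params.Qmax), params, lpar, dt=0.1
        )
        for col in ("EG_frac", "ECK1_frac", "ECK2_frac"):
            assert res.data[col].iloc[0] == 1.0

    def test_model2_store_closes_with_qa(self, recovery_run, params, lpar):
        aer, lac = recovery_run
        eck2 = params.theta * (aer.Qa - aer.Qa[0])
        frac = 1.0 - eck2 / (params.E_CK0 * params.m)
        assert frac[0] == 1.0
        assert frac[-1] == pytest.approx(1.0, abs=1e-9)

    def test_continuous_exercise_store_shapes(self, params, lpar):
        """Model 1's alactic store has an interior minimum near the time the
        aerobic power reaches steady state; Model 2's declines monotonically
        while loading."""
        prof = continuous_profile(params.Qmax, 0.87, 360.0, 5)
        res = run_simulation(prof, params, lpar, dt=0.1)
        d = res.data
        i_min = int(np.argmin(d["ECK1_frac"].to_numpy()))
        assert 0 < i_min < len(d) - 1  # strictly interior
        # near aerobic steady state: within a few e-folding times of the ramp top
        assert d["t"].iloc[i_min] < 360.0
        assert np.all(np.diff(d["ECK2_frac"].to_numpy()) <= 1e-12)
        assert d["ECK2_frac"].iloc[-1] <= d["ECK2_frac"].min() + 1e-9

    def test_interval_exercise_restores_stores_between_periods(self, params, lpar):
        """Once the start-up transient has settled (from the third period
        on), lactate and both alactic stores return to within 5% at each
        period boundary."""
        prof = interval_profile(params.Qmax, 360.0, 5)
        res = run_simulation(prof, params, lpar, dt=0.1)
        d = res.data
        aer = res.aerobic
        for k in range(2, 5):
            i0 = aer.index_of(360.0 * k)
            i1 = aer.index_of(360.0 * (k + 1))
            assert d["C"].iloc[i1] == pytest.approx(d["C"].iloc[i0], rel=0.05)
            for col in ("ECK1_frac", "ECK2_frac"):
                assert d[col].iloc[i1] == pytest.approx(d[col].iloc[i0], rel=0.05)
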