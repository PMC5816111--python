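"""Linear compartment solver: closed-form and fine-integrator oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from iodair import biokinetics as bk
from iodair import deposition as dep
from iodair import scenario as sc
from iodair.air_sampling import I131

LAMBDA = I131.decay_constant


def rates_file(tmp_path, rows):
    path = tmp_path / "rates.csv"
    header = "from_compartment,to_compartment,rate_per_day,form,provenance\n"
    path.write_text(header + "".join(f"{a},{b},{k},both,test\n" for a, b, k in rows))
    return path


def single_region_table(region):
    return dep.DepositionTable(entries={("male", "gas"): {region: 1.0}})


def one_bolus(model, deposit, horizon, samples=200):
    timeline = sc.IntakeTimeline(
        events=(sc.IntakeEvent(start_time=0.0, duration=1.0, inhaled_gas=1.0, inhaled_aerosol=0.0),)
    )
    return bk.solve(model, timeline, deposit, horizon, samples_per_interval=samples)


class TestDecayOnly:
    def test_pure_decay_half_life(self, tmp_path):
        """With all transfers zeroed, a 1000-Bq bolus halves in 8.03 d."""
        model = bk.build_iodine_model("male", "gas", rates_path=rates_file(tmp_path, []))
        deposit = dep.regional_deposition(1000.0, "male", "gas", single_region_table("ET1"))
        traj = one_bolus(model, deposit, horizon=8.03)
        assert traj.compartment("ET1")[-1] == pytest.approx(500.0, rel=1e-9)

    def test_committed_closed_form(self, tmp_path):
        """Isolated decaying compartment: U = A0 / lambda = 11585 Bq d."""
        model = bk.build_iodine_model("male", "gas", rates_path=rates_file(tmp_path, []))
        deposit = dep.regional_deposition(1000.0, "male", "gas", single_region_table("ET1"))
        u = bk.integrate_committed(model, deposit)
        assert u.by_source["ET"] == pytest.approx(1000.0 / LAMBDA, rel=1e-9)
        assert u.by_source["ET"] == pytest.approx(11585, rel=1e-3)

    def test_zero_deposit_all_zero(self):
        model = bk.build_iodine_model("male", "gas")
        u = bk.integrate_committed(model, dep.RegionalDeposit(deposits={}, exhaled=0.0))
        assert all(v == 0.0 for v in u.by_source.values())


class TestBatemanOracle:
    def test_two_compartment_chain(self, tmp_path):
        """ET2 -> blood chain matches the Bateman closed form to 1e-8."""
        k = 3.0
        model = bk.build_iodine_model(
            "male", "gas", rates_path=rates_file(tmp_path, [("ET2", "blood", k)])
        )
        deposit = dep.regional_deposition(1.0, "male", "gas", single_region_table("ET2"))
        traj = one_bolus(model, deposit, horizon=10.0, samples=50)
        t = traj.times
        parent = np.exp(-(k + LAMBDA) * t)
        daughter = np.exp(-LAMBDA * t) - np.exp(-(k + LAMBDA) * t)
        assert traj.compartment("ET2") == pytest.approx(parent, rel=1e-8, abs=1e-12)
        assert traj.compartment("blood") == pytest.approx(daughter, rel=1e-8, abs=1e-12)


@pytest.fixture(scope="module")
def gas_model():
    return bk.build_iodine_model("male", "gas")


@pytest.fixture(scope="module")
def unit_gas_deposit():
    return dep.regional_deposition(1.0, "male", "gas")


class TestFullModel:
    def test_against_fine_step_integrator(self, gas_model, unit_gas_deposit):
        """Matrix-exponential route vs a high-accuracy ODE integrator, 1e-6."""
        traj = one_bolus(gas_model, unit_gas_deposit, horizon=30.0, samples=120)
        a0 = bk.initial_vector(gas_model, unit_gas_deposit)
        sol = solve_ivp(
            lambda t, y: gas_model.matrix @ y,
            (0.0, 30.0),
            a0,
            t_eval=traj.times,
            rtol=1e-11,
            atol=1e-14,
            method="LSODA",
        )
        scale = np.abs(sol.y).max()
        assert np.max(np.abs(traj.activities.T - sol.y)) / scale < 1e-6

    def test_activity_balance(self, gas_model, unit_gas_deposit):
        """compartments + excreted + decayed == intake at all times, 1e-8."""
        traj = one_bolus(gas_model, unit_gas_deposit, horizon=60.0)
        totals = traj.activities.sum(axis=1)
        assert np.allclose(totals, traj.total_intake, rtol=1e-8)

    def test_non_negativity(self, gas_model, unit_gas_deposit):
        traj = one_bolus(gas_model, unit_gas_deposit, horizon=60.0)
        assert traj.activities.min() > -1e-12

    def test_linearity_in_intake(self, gas_model):
        d1 = dep.regional_deposition(1.0, "male", "gas")
        d7 = dep.regional_deposition(7.0, "male", "gas")
        u1 = bk.integrate_committed(gas_model, d1)
        u7 = bk.integrate_committed(gas_model, d7)
        for s in u1.by_source:
            assert u7.by_source[s] == pytest.approx(7 * u1.by_source[s], rel=1e-12)

    def test_committed_vs_quadrature_oracle(self, gas_model, unit_gas_deposit):
        """Thyroid U equals adaptive quadrature of the trajectory to 1e-6."""
        from scipy.linalg import expm

        nb = gas_model.n_body
        mb = gas_model.body_matrix
        a0 = bk.initial_vector(gas_model, unit_gas_deposit)[:nb]
        i_thy = gas_model.compartments.index("thyroid")

        def thy(t):
            return (expm(mb * t) @ a0)[i_thy]

        oracle, _ = quad(thy, 0.0, 400.0, limit=400)
        u = bk.integrate_committed(gas_model, unit_gas_deposit)
        assert u.by_source["thyroid"] == pytest.approx(oracle, rel=1e-6)

    def test_total_integrated_bounded_by_intake_over_lambda(self, gas_model, unit_gas_deposit):
        u = bk.integrate_committed(gas_model, unit_gas_deposit)
        assert sum(u.by_source.values()) <= 1.0 / LAMBDA * (1 + 1e-12)

    def test_commitment_period_insensitivity(self, gas_model, unit_gas_deposit):
        """For an 8-d nuclide, 1-y and 50-y committed integrals coincide."""
        u1 = bk.integrate_committed(gas_model, unit_gas_deposit, commit_period=365.0)
        u50 = bk.integrate_committed(gas_model, unit_gas_deposit, commit_period=18250.0)
        for s, v50 in u50.by_source.items():
            if v50 > 0:
                assert u1.by_source[s] / v50 >= 0.9999

    def test_fast_absorption_of_vapour(self, gas_model, unit_gas_deposit):
        """ET2/BB vapour deposits reach blood with half-time << 1 d."""
        traj = one_bolus(gas_model, unit_gas_deposit, horizon=1.0)
        t_idx = np.searchsorted(traj.times, 0.25)
        assert traj.compartment("ET2")[t_idx] < 1e-8  # gone well before a day
        assert traj.compartment("BB_fast")[t_idx] < 1e-8

    def test_gas_model_has_no_deep_lung_deposit(self, unit_gas_deposit):
        assert unit_gas_deposit.deposits["AI"] == 0.0
        assert unit_gas_deposit.deposits["bb_fast_seq"] == 0.0

    def test_nonfinite_rates_rejected(self, tmp_path):
        with pytest.raises(bk.ModelError):
            bk.build_iodine_model(
                "male", "gas", rates_path=rates_file(tmp_path, [("ET2", "blood", "nan")])
            )


class TestTrajectoriesAndPlateau:
    def test_thyroid_activity_interpolation_and_domain(self, gas_model, unit_gas_deposit):
        traj = one_bolus(gas_model, unit_gas_deposit, horizon=10.0)
        assert bk.thyroid_activity(traj, 0.0) == 0.0  # bolus lands in the airways
        with pytest.raises(ValueError):
            bk.thyroid_activity(traj, 11.0)

    def test_plateau_linearity_in_concentration(self):
        s1 = sc.ExposureScenario.default("nurse", "male")
        s2 = sc.ExposureScenario(
            "nurse", s1.subject, 2 * s1.gas_concentration, 2 * s1.aerosol_concentration,
            s1.hours_per_intake, s1.intakes_per_year, s1.intake_spacing,
        )
        p1 = bk.plateau_thyroid_activity(s1, n_intakes=10)
        p2 = bk.plateau_thyroid_activity(s2, n_intakes=10)
        assert p2 == pytest.approx(2 * p1, rel=1e-10)

    def test_repeated_intakes_conserve_activity(self, gas_model):
        s = sc.ExposureScenario.default("nurse", "male")
        timeline = sc.build_timeline(s, horizon=30.0)
        deposit = dep.regional_deposition(sc.single_intake(s, "gas"), "male", "gas")
        traj = bk.solve(gas_model, timeline, deposit, horizon=30.0)
        totals = traj.activities.sum(axis=1)
        assert totals[-1] == pytest.approx(traj.total_intake, rel=1e-8)
        assert traj.total_intake == pytest.approx(10 * (sc.single_intake(s, "gas")))
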