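import math

import numpy as np
import pytest

import qualdyn as q
from qualdyn import ode
from qualdyn.ode import (
    KineticParameters,
    brn_to_ode,
    equilibrium,
    load_demo_kinetics,
    sensitivity,
    simulate,
)


@pytest.fixture(scope="module")
def unregulated():
    """One species with no regulators: dx/dt = beta - gamma*x, closed form
    x(t) = (beta/gamma)(1 - exp(-gamma t)) from x0 = 0."""
    net = q.build_network([("s", 1)], [])
    kin = KineticParameters(beta={"s": 1.0}, gamma={"s": 0.5}, x0={"s": 0.0})
    return brn_to_ode(net, kin)


class TestTranslation:
    def test_unregulated_rhs(self, unregulated):
        assert unregulated.rhs(0.0, np.array([0.0]))[0] == pytest.approx(1.0)
        assert unregulated.rhs(0.0, np.array([2.0]))[0] == pytest.approx(0.0)

    def test_hill_half_max_single_activator(self):
        net = q.build_network([("u", 1), ("v", 1)], [("u", "v", "+", 1), ("v", "u", "+", 1)])
        kin = KineticParameters.uniform(net, theta=0.4, hill=3.0)
        system = brn_to_ode(net, kin, mode="product")
        dx = system.rhs(0.0, np.array([0.4, 0.0]))
        assert dx[1] == pytest.approx(0.5)  # activator exactly at threshold

    def test_logic_mode_reduces_to_hill_for_canonical_table(self):
        net = q.build_network([("u", 1), ("v", 1)], [("u", "v", "+", 1), ("v", "u", "+", 1)])
        params = q.ParameterSet(
            {
                "u": {frozenset(): 0, frozenset({"v"}): 1},
                "v": {frozenset(): 0, frozenset({"u"}): 1},
            }
        )
        kin = KineticParameters.uniform(net, theta=0.4, hill=3.0)
        logic = brn_to_ode(q.ModelInstance(net, params), kin, mode="logic")
        product = brn_to_ode(net, kin, mode="product")
        for x in ([0.1, 0.7], [0.4, 0.4], [0.9, 0.2]):
            assert logic.rhs(0.0, np.array(x)) == pytest.approx(
                product.rhs(0.0, np.array(x))
            )

    def test_case_study_system_structure(self, hif1_model):
        kin = KineticParameters.uniform(hif1_model.network)
        system = brn_to_ode(hif1_model, kin)
        assert len(system.species) == 9
        # sign-product mode: HIF-1's regulation carries an activating ERK
        # factor and an inhibiting p53 factor
        product = brn_to_ode(hif1_model.network, kin, mode="product")
        base = np.full(9, 0.5)
        i_h = product.species.index("HIF-1")
        up_erk = base.copy(); up_erk[product.species.index("ERK")] = 1.0
        up_p53 = base.copy(); up_p53[product.species.index("p53")] = 1.0
        assert product.rhs(0.0, up_erk)[i_h] > product.rhs(0.0, base)[i_h]
        assert product.rhs(0.0, up_p53)[i_h] < product.rhs(0.0, base)[i_h]

    def test_missing_kinetics_raise(self):
        net = q.build_network([("a", 1), ("b", 1)], [("a", "b", "+", 1), ("b", "a", "+", 1)])
        kin = KineticParameters(beta={"a": 1.0}, gamma={"a": 1.0}, x0={"a": 0.0})
        with pytest.raises(ValueError):
            brn_to_ode(net, kin, mode="product")


class TestSimulate:
    def test_matches_closed_form_to_1e6(self, unregulated):
        traj = simulate(unregulated, 2.0, n_points=21)
        expected = 2.0 * (1.0 - np.exp(-0.5 * traj.times))
        rel = np.abs(traj.concentrations[0, 1:] - expected[1:]) / expected[1:]
        assert rel.max() < 1e-6

    def test_approaches_beta_over_gamma(self, unregulated):
        traj = simulate(unregulated, 50.0)
        assert traj.concentrations[0, -1] == pytest.approx(2.0, rel=1e-6)

    def test_nonnegative_and_bounded(self, hif1_model):
        kin = load_demo_kinetics("demo_c")
        system = brn_to_ode(hif1_model, kin)
        traj = simulate(system, 30.0)
        assert (traj.concentrations >= 0).all()
        for i, name in enumerate(system.species):
            bound = kin.beta[name] / kin.gamma[name]
            assert traj.concentrations[i].max() <= bound + 1e-6

    def test_invalid_t_end(self, unregulated):
        with pytest.raises(ValueError):
            simulate(unregulated, 0.0)


class TestEquilibrium:
    def test_unregulated_equilibrium(self, unregulated):
        assert equilibrium(unregulated)[0] == pytest.approx(2.0, abs=1e-8)

    def test_symmetric_mutual_activation(self):
        net = q.build_network(
            [("x1", 1), ("x2", 1)], [("x1", "x2", "+", 1), ("x2", "x1", "+", 1)]
        )
        kin = KineticParameters.uniform(net, x0=0.8)
        system = brn_to_ode(net, kin, mode="product")
        eq = equilibrium(system)
        assert eq[0] == pytest.approx(eq[1], abs=1e-8)

    def test_demo_d_residual_within_tolerance(self, hif1_model):
        system = brn_to_ode(hif1_model, load_demo_kinetics("demo_d"))
        eq = equilibrium(system, tol=1e-8)
        assert np.max(np.abs(system.rhs(0.0, eq))) <= 1e-8


class TestSensitivity:
    def test_production_rate_unit_sensitivity(self, unregulated):
        assert sensitivity(unregulated, "s", ("beta", "s")) == pytest.approx(1.0, abs=1e-4)

    def test_degradation_rate_negative_unit_sensitivity(self, unregulated):
        assert sensitivity(unregulated, "s", ("gamma", "s")) == pytest.approx(-1.0, abs=1e-3)

    def test_glut1_responds_positively_to_erk_production(self, hif1_model):
        system = brn_to_ode(hif1_model, load_demo_kinetics("demo_c"))
        coeff = sensitivity(system, "GLUT-1", ("beta", "ERK"), target="equilibrium")
        assert coeff > 0

    def test_invalid_delta(self, unregulated):
        with pytest.raises(ValueError):
            sensitivity(unregulated, "s", ("beta", "s"), delta=0.9)


class TestDemoScenarios:
    def test_demo_b_pulse_and_relaxation(self, hif1_model):
        """VEGF and HIF-1 rise then decay toward zero; VEGF clears faster
        than ERK degrades, so the end-time ordering is VEGF < ERK."""
        kin = load_demo_kinetics("demo_b")
        system = brn_to_ode(hif1_model, kin)
        traj = simulate(system, 20.0)
        s = {n: i for i, n in enumerate(system.species)}
        final = traj.final()
        for name in ("VEGF", "HIF-1"):
            series = traj.concentrations[s[name]]
            assert series.max() > kin.x0[name] + 0.02  # a genuine pulse
            assert final[name] < 0.1
        assert final["VEGF"] < final["ERK"]

    @pytest.mark.parametrize("scenario", ["pathogenic", "recovery"])
    def test_equilibrium_pattern_matches_logical_attractor(
        self, hif1_model, hif1_fixtures, scenario
    ):
        """Thresholding the ODE equilibrium at each species' half-maximum
        reproduces the logical stable state of the matching basin."""
        kin = load_demo_kinetics(scenario)
        system = brn_to_ode(hif1_model, kin)
        eq = equilibrium(system, tol=1e-8)
        pattern = tuple(
            int(x > kin.beta[n] / (2.0 * kin.gamma[n]))
            for x, n in zip(eq, system.species)
        )
        expected = (
            hif1_fixtures.deadlock if scenario == "pathogenic" else hif1_fixtures.recovery
        )
        assert pattern == expected

    def test_unknown_scenario_raises(self):
        with pytest.raises(ValueError):
            load_demo_kinetics("demo_z")


def test_kinetics_yaml_roundtrip(tmp_path, hif1_model):
    kin = load_demo_kinetics("demo_a")
    path = tmp_path / "k.yaml"
    kin.to_yaml(path)
    back = KineticParameters.from_yaml(path)
    assert back.beta == kin.beta
    assert back.theta == kin.theta
    assert back.x0 == kin.x0
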