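"""ODE compilation and integration semantics."""

import numpy as np
import pytest
from scipy.linalg import null_space

from sbmlkit.errors import ModelCompileError
from sbmlkit.fixtures import make_fixture, random_network
from sbmlkit.mathml import apply_op, num, sym, TimeSymbol
from sbmlkit.model import KineticLaw, Model, Rule, SpeciesReference
from sbmlkit.ode import build_ode_system, simulate_ode


class TestBuild:
    def test_decay_structure(self):
        doc = make_fixture("decay")
        system = build_ode_system(doc.model)
        assert system.state_ids == ["A", "B"]
        assert np.allclose(system.stoichiometry, [[-1.0], [1.0]])
        assert np.allclose(system.initial_state, [10.0, 0.0])

    def test_boundary_species_frozen(self):
        doc = make_fixture("decay")
        doc.model.species[0].boundary_condition = True
        system = build_ode_system(doc.model)
        tc = simulate_ode(system, 1.0, n_out=5)
        assert np.allclose(tc["A"], 10.0)
        # B still accumulates at constant rate k*A0
        assert tc["B"][-1] == pytest.approx(5.0, rel=1e-6)

    def test_concentration_convention(self):
        """With compartment size 2 and a concentration-view species, the
        law sees A as amount/2, so decay slows to rate k/2."""
        doc = make_fixture("decay")
        doc.model.compartments[0].size = 2.0
        for s in doc.model.species:
            s.has_only_substance_units = False
        system = build_ode_system(doc.model)
        tc = simulate_ode(system, 2.0, n_out=5, rtol=1e-10, atol=1e-12)
        # d(amount A)/dt = -k * (A/2)  ->  amount A(t) = 10 exp(-t/4)
        amount_a = tc["A"][-1] * 2.0  # column reports concentration
        assert amount_a == pytest.approx(10.0 * np.exp(-0.5), rel=1e-6)

    def test_missing_kinetic_law_is_compile_error(self):
        doc = make_fixture("decay")
        doc.model.reactions[0].kinetic_law = None
        with pytest.raises(ModelCompileError):
            build_ode_system(doc.model)

    def test_assignment_cycle_is_compile_error(self):
        doc = make_fixture("decay")
        m = doc.model
        m.add_parameter("u", value=0.0, constant=False)
        m.add_parameter("w", value=0.0, constant=False)
        m.rules.append(Rule("assignment", "u", sym("w")))
        m.rules.append(Rule("assignment", "w", sym("u")))
        with pytest.raises(ModelCompileError):
            build_ode_system(m)

    def test_initial_assignment_overrides_literal(self):
        doc = make_fixture("decay")
        from sbmlkit.model import InitialAssignment
        doc.model.initial_assignments.append(
            InitialAssignment(symbol="A", math=num(4.0))
        )
        system = build_ode_system(doc.model)
        assert system.initial_state[0] == 4.0


class TestSimulate:
    def test_exponential_decay_closed_form(self):
        doc = make_fixture("decay")
        tc = simulate_ode(build_ode_system(doc.model), 2.0, n_out=21,
                          rtol=1e-9, atol=1e-12)
        assert tc["A"][-1] == pytest.approx(10.0 * np.exp(-1.0), rel=1e-6)

    def test_mass_conservation(self):
        doc = make_fixture("decay")
        tc = simulate_ode(build_ode_system(doc.model), 2.0, n_out=21,
                          rtol=1e-9, atol=1e-12)
        assert np.allclose(tc["A"] + tc["B"], 10.0, atol=1e-6)

    def test_michaelis_menten_monotone_and_conserved(self):
        doc = make_fixture("michaelis")
        tc = simulate_ode(build_ode_system(doc.model), 5.0, n_out=51,
                          rtol=1e-9, atol=1e-12)
        assert np.all(np.diff(tc["S"]) < 0)
        assert np.all(np.diff(tc["P"]) > 0)
        assert np.allclose(tc["S"] + tc["P"], 10.0, atol=1e-6)

    def test_tolerance_convergence(self):
        """Halving the tolerances changes the endpoint by less than the
        coarser tolerance."""
        doc = make_fixture("decay")
        system = build_ode_system(doc.model)
        coarse = simulate_ode(system, 2.0, n_out=3, rtol=1e-6, atol=1e-9)
        fine = simulate_ode(system, 2.0, n_out=3, rtol=5e-7, atol=5e-10)
        delta = abs(coarse["A"][-1] - fine["A"][-1]) / fine["A"][-1]
        assert delta < 1e-6

    def test_output_grid(self):
        doc = make_fixture("decay")
        tc = simulate_ode(build_ode_system(doc.model), 2.0, n_out=5)
        assert np.allclose(tc.times, [0.0, 0.5, 1.0, 1.5, 2.0])
        assert list(tc.data.columns) == ["time", "A", "B"]

    def test_invalid_arguments(self):
        system = build_ode_system(make_fixture("decay").model)
        with pytest.raises(ValueError):
            simulate_ode(system, -1.0)
        with pytest.raises(ValueError):
            simulate_ode(system, 1.0, n_out=1)


class TestEvents:
    def test_assignment_discontinuity(self):
        doc = make_fixture("decay_event")
        tc = simulate_ode(build_ode_system(doc.model), 2.0, n_out=41,
                          rtol=1e-9, atol=1e-12)
        assert len(tc.event_times) == 1
        assert tc.event_times[0] == pytest.approx(1.0, abs=1e-9)
        after = tc.data[tc.data.time > 1.0 - 1e-12].iloc[0]
        assert after["A"] == pytest.approx(10.0, rel=1e-9)

    def test_delayed_event(self):
        doc = make_fixture("decay_event")
        doc.model.events[0].delay = num(0.5)
        tc = simulate_ode(build_ode_system(doc.model), 2.0, n_out=41,
                          rtol=1e-9, atol=1e-12)
        assert tc.event_times[0] == pytest.approx(1.5, abs=1e-8)

    def test_use_values_from_trigger_time(self):
        """A := B evaluated at trigger time, not execution time."""
        doc = make_fixture("decay_event")
        ev = doc.model.events[0]
        ev.delay = num(0.5)
        ev.use_values_from_trigger_time = True
        ev.assignments[0].math = sym("B")
        tc = simulate_ode(build_ode_system(doc.model), 2.0, n_out=201,
                          rtol=1e-10, atol=1e-12)
        b_at_1 = 10.0 * (1 - np.exp(-0.5))
        after = tc.data[tc.data.time > 1.5 - 1e-12].iloc[0]
        assert after["A"] == pytest.approx(b_at_1, rel=1e-6)

    def test_initial_value_false_fires_at_zero(self):
        doc = make_fixture("decay_event")
        ev = doc.model.events[0]
        ev.trigger.math = apply_op("geq", TimeSymbol(), num(0.0))
        ev.trigger.initial_value = False
        tc = simulate_ode(build_ode_system(doc.model), 1.0, n_out=11)
        assert tc.event_times[0] == pytest.approx(0.0, abs=1e-9)


def test_left_null_vectors_conserved_on_random_closed_networks():
    """Every left null vector of the stoichiometry matrix stays constant
    along the trajectory of a closed network."""
    for seed in (11, 12, 13):
        doc = random_network(6, 3, seed=seed)
        system = build_ode_system(doc.model)
        tc = simulate_ode(system, 1.0, n_out=11, rtol=1e-10, atol=1e-12)
        ns = null_space(system.stoichiometry.T)
        amounts = tc.data[system.state_ids].to_numpy()
        for k in range(ns.shape[1]):
            vals = amounts @ ns[:, k]
            scale = max(1.0, abs(vals[0]))
            assert np.max(np.abs(vals - vals[0])) / scale < 1e-6


def test_rate_rule_on_parameter():
    m = Model(id="rr")
    m.add_compartment("c", size=1.0)
    m.add_parameter("p", value=0.0, constant=False)
    m.add_parameter("k", value=2.0, constant=True)
    m.rules.append(Rule("rate", "p", sym("k")))
    tc = simulate_ode(build_ode_system(m), 3.0, n_out=4,
                      rtol=1e-10, atol=1e-12)
    assert tc["p"][-1] == pytest.approx(6.0, rel=1e-8)


def test_assignment_rule_holds_at_all_times():
    doc = make_fixture("decay")
    m = doc.model
    m.add_parameter("total", value=0.0, constant=False)
    m.rules.append(
        Rule("assignment", "total", apply_op("plus", sym("A"), sym("B"))))
    tc = simulate_ode(build_ode_system(m), 2.0, n_out=11,
                      rtol=1e-9, atol=1e-12)
    assert np.allclose(tc["total"], 10.0, atol=1e-6)
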