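"""Gillespie direct-method semantics and statistics."""

import numpy as np
import pytest
from scipy import stats

from sbmlkit.errors import SbmlError, UnsupportedModelError
from sbmlkit.fixtures import make_fixture
from sbmlkit.mathml import apply_op, num, sym
from sbmlkit.model import KineticLaw, Model, SpeciesReference
from sbmlkit.ode import build_ode_system, simulate_ode
from sbmlkit.ssa import replicate_mean, sidecar_json, simulate_ssa


class TestPreconditions:
    def test_concentration_species_rejected(self):
        doc = make_fixture("ssa_death")
        doc.model.species[0].has_only_substance_units = False
        with pytest.raises(UnsupportedModelError):
            simulate_ssa(doc.model, 1.0, seed=1)

    def test_rules_rejected(self):
        doc = make_fixture("ssa_death")
        from sbmlkit.model import Rule
        doc.model.rules.append(Rule("rate", "A", num(1)))
        with pytest.raises(UnsupportedModelError):
            simulate_ssa(doc.model, 1.0, seed=1)

    def test_non_integer_initial_amount_rejected(self):
        doc = make_fixture("ssa_death", {"A0": 10.5})
        with pytest.raises(UnsupportedModelError):
            simulate_ssa(doc.model, 1.0, seed=1)

    def test_negative_propensity_rejected(self):
        doc = make_fixture("ssa_death", {"k": -1.0})
        with pytest.raises(SbmlError):
            simulate_ssa(doc.model, 1.0, seed=1)


class TestTrajectories:
    def test_seed_determinism(self):
        doc = make_fixture("ssa_death")
        a = simulate_ssa(doc.model, 1.0, seed=42)
        b = simulate_ssa(doc.model, 1.0, seed=42)
        assert (a.data.values == b.data.values).all()

    def test_different_seeds_differ(self):
        doc = make_fixture("ssa_death")
        a = simulate_ssa(doc.model, 1.0, seed=1)
        b = simulate_ssa(doc.model, 1.0, seed=2)
        assert not (a.data.values == b.data.values).all()

    def test_absorbing_state_constant(self):
        doc = make_fixture("ssa_death", {"A0": 0.0})
        tc = simulate_ssa(doc.model, 5.0, seed=3)
        assert (tc["A"] == 0).all()

    def test_counts_are_nonnegative_integers(self):
        doc = make_fixture("ssa_death")
        tc = simulate_ssa(doc.model, 2.0, seed=5)
        values = tc.data.drop(columns="time").to_numpy()
        assert values.dtype.kind == "i"
        assert (values >= 0).all()

    def test_sidecar_metadata(self):
        doc = make_fixture("ssa_death")
        tc = simulate_ssa(doc.model, 1.0, seed=9, replicate=4)
        sidecar = sidecar_json(tc)
        assert '"seed": 9' in sidecar
        assert '"replicate": 4' in sidecar
        assert "PCG64" in sidecar


class TestStatistics:
    def test_death_process_mean(self):
        """Linear death process: E[A(1)] = A0 e^{-k}, checked to 3 SE over
        1000 replicates."""
        doc = make_fixture("ssa_death")
        n_rep = 1000
        finals = np.empty(n_rep)
        for r in range(n_rep):
            tc = simulate_ssa(doc.model, 1.0, seed=2024, n_out=2, replicate=r)
            finals[r] = tc["A"][-1]
        p = np.exp(-0.5)
        expected = 100.0 * p
        se = np.sqrt(100.0 * p * (1 - p) / n_rep)
        assert abs(finals.mean() - expected) < 3 * se

    def test_waiting_times_exponential(self):
        """Constant-propensity (zeroth-order) reaction: inter-event times
        follow Exponential(lambda) by a KS test at level 0.01."""
        lam = 2.0
        m = Model(id="birth")
        m.add_compartment("c", size=1.0)
        m.add_species("X", "c", initial_amount=0.0,
                      has_only_substance_units=True)
        m.add_parameter("lam", value=lam, constant=True)
        m.add_reaction(
            "birth",
            products=[SpeciesReference("X")],
            kinetic_law=KineticLaw(math=sym("lam")),
        )
        n_events = 10_000
        t_end = (n_events + 500) / lam
        tc = simulate_ssa(m, t_end, seed=7, n_out=2,
                          collect_event_times=True)
        times = tc.metadata["event_times"][:n_events]
        inter = np.diff(np.concatenate([[0.0], times]))
        result = stats.kstest(inter, "expon", args=(0, 1.0 / lam))
        assert result.pvalue > 0.01

    def test_mean_trajectory_matches_ode_at_large_numbers(self):
        """Law of large numbers: SSA replicate mean of the decay fixture at
        A0=10000 tracks the ODE solution within 1% at t in {0.5, 1, 2}."""
        doc = make_fixture("decay", {"A0": 10_000.0})
        n_out = 5  # grid 0, 0.5, 1, 1.5, 2
        mean = replicate_mean(doc.model, 2.0, seed=99, n_replicates=200,
                              n_out=n_out)
        ode_tc = simulate_ode(build_ode_system(doc.model), 2.0, n_out=n_out,
                              rtol=1e-10, atol=1e-12)
        for t_idx in (1, 2, 4):  # 0.5, 1.0, 2.0
            ssa_val = mean["A"].iloc[t_idx]
            ode_val = ode_tc["A"][t_idx]
            assert abs(ssa_val - ode_val) / ode_val < 0.01
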