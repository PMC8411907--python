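"""Flux balance constraints: LP construction, FBA, FVA, GPAs."""

import numpy as np
import pytest

from conftest import brute_force_fva, brute_force_lp
from sbmlkit.errors import ModelCompileError
from sbmlkit.fbc import (
    build_lp,
    evaluate_gpa,
    flux_variability,
    fluxes_to_tsv,
    gpa_and,
    gpa_or,
    gpa_ref,
    solve_fba,
)
from sbmlkit.fixtures import make_fixture, random_fbc_network


class TestBuildLP:
    def test_chain_structure(self):
        lp = build_lp(make_fixture("chain_fbc").model)
        assert lp.species_ids == ["A", "B"]
        assert lp.reaction_ids == ["v1", "v2", "v3"]
        assert np.allclose(lp.S, [[1, -1, 0], [0, 1, -1]])
        assert np.allclose(lp.c, [0, 0, 1])
        assert lp.sense == "max"
        assert np.allclose(lp.lb, 0) and np.allclose(lp.ub, [10, 1000, 1000])

    def test_reversible_bounds_pass_through(self):
        doc = make_fixture("chain_fbc")
        m = doc.model
        m.add_parameter("neg", value=-1000.0, constant=True)
        m.reactions[1].lower_flux_bound = "neg"
        lp = build_lp(m)
        assert lp.lb[1] == -1000.0

    def test_no_fbc_extension(self):
        with pytest.raises(ModelCompileError):
            build_lp(make_fixture("decay").model)

    def test_missing_bound_parameter(self):
        doc = make_fixture("chain_fbc")
        doc.model.reactions[0].upper_flux_bound = "ghost"
        with pytest.raises(ModelCompileError, match="E3001"):
            build_lp(doc.model)

    def test_no_active_objective(self):
        doc = make_fixture("chain_fbc")
        doc.model.fbc.active_objective = "ghost"
        with pytest.raises(ModelCompileError, match="E3002"):
            build_lp(doc.model)


class TestFBA:
    def test_chain_optimum(self):
        result = solve_fba(make_fixture("chain_fbc").model)
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(10.0, abs=1e-7)
        for rid in ("v1", "v2", "v3"):
            assert result.fluxes[rid] == pytest.approx(10.0, abs=1e-7)

    def test_mass_balance_of_solution(self):
        doc = make_fixture("chain_fbc")
        lp = build_lp(doc.model)
        result = solve_fba(doc.model)
        v = np.array([result.fluxes[r] for r in lp.reaction_ids])
        assert np.max(np.abs(lp.S @ v)) <= 1e-9
        assert np.all(v >= lp.lb - 1e-9) and np.all(v <= lp.ub + 1e-9)

    def test_gene_knockout_zeroes_objective(self):
        result = solve_fba(make_fixture("chain_fbc").model, knockouts={"g1"})
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_when_demand_exceeds_supply(self):
        doc = make_fixture("chain_fbc")
        doc.model.add_parameter("force20", value=20.0, constant=True)
        doc.model.reactions[2].lower_flux_bound = "force20"
        assert solve_fba(doc.model).status == "infeasible"

    def test_undeclared_knockout_rejected(self):
        with pytest.raises(ModelCompileError):
            solve_fba(make_fixture("chain_fbc").model, knockouts={"gX"})


class TestGPA:
    def test_and_or_semantics(self):
        gpa = gpa_or(gpa_and(gpa_ref("g1"), gpa_ref("g2")), gpa_ref("g3"))
        assert evaluate_gpa(gpa, {"g3"}) is True
        assert evaluate_gpa(gpa, {"g1"}) is False
        assert evaluate_gpa(gpa, {"g1", "g2"}) is True

    def test_leaf(self):
        assert evaluate_gpa(gpa_ref("g1"), set()) is False

    def test_empty_children_rejected(self):
        from sbmlkit.fbc import GPA
        with pytest.raises(ModelCompileError):
            GPA(and_=[])


class TestFVA:
    def test_fraction_one_pins_bottleneck(self):
        ranges = flux_variability(make_fixture("chain_fbc").model, 1.0)
        assert ranges["v2"]["min"] == pytest.approx(10.0, abs=1e-7)
        assert ranges["v2"]["max"] == pytest.approx(10.0, abs=1e-7)

    def test_fraction_half_relaxes_exit(self):
        ranges = flux_variability(make_fixture("chain_fbc").model, 0.5)
        assert ranges["v3"]["min"] == pytest.approx(5.0, abs=1e-7)
        assert ranges["v3"]["max"] == pytest.approx(10.0, abs=1e-7)

    def test_degenerate_bounds_pin_flux(self):
        doc = make_fixture("chain_fbc")
        m = doc.model
        m.add_parameter("three", value=3.0, constant=True)
        m.reactions[0].lower_flux_bound = "three"
        m.reactions[0].upper_flux_bound = "three"
        ranges = flux_variability(m, 0.5)
        assert ranges["v1"]["min"] == pytest.approx(3.0, abs=1e-7)
        assert ranges["v1"]["max"] == pytest.approx(3.0, abs=1e-7)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            flux_variability(make_fixture("chain_fbc").model, 0.0)

    def test_matches_vertex_oracle_on_chain(self):
        lp = build_lp(make_fixture("chain_fbc").model)
        lo, hi = brute_force_fva(lp.S, lp.lb, lp.ub, lp.c, 0.5)
        ranges = flux_variability(make_fixture("chain_fbc").model, 0.5)
        for j, rid in enumerate(lp.reaction_ids):
            assert ranges[rid]["min"] == pytest.approx(lo[j], abs=1e-7)
            assert ranges[rid]["max"] == pytest.approx(hi[j], abs=1e-7)


class TestRandomNetworks:
    @pytest.mark.parametrize("seed", range(10))
    def test_objective_matches_vertex_enumeration(self, seed):
        doc = random_fbc_network(4, 5, seed=seed)
        lp = build_lp(doc.model)
        expected = brute_force_lp(lp.S, lp.lb, lp.ub, lp.c, lp.sense)
        result = solve_fba(doc.model)
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(expected, abs=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_tightening_a_bound_never_improves_the_optimum(self, seed):
        doc = random_fbc_network(4, 5, seed=seed)
        base = solve_fba(doc.model).objective_value
        m = doc.model
        for j, r in enumerate(m.reactions):
            ub = m.parameter_by_id(r.upper_flux_bound)
            original = ub.value
            ub.value = original / 2.0
            tightened = solve_fba(m)
            if tightened.status == "optimal":
                assert tightened.objective_value <= base + 1e-7
            ub.value = original


def test_tsv_export():
    doc = make_fixture("chain_fbc")
    result = solve_fba(doc.model)
    fva = flux_variability(doc.model, 1.0)
    tsv = fluxes_to_tsv(doc.model, result, fva)
    header, *rows = tsv.strip().split("\n")
    assert header.split("\t") == [
        "reaction_id", "flux", "lower_bound", "upper_bound", "min", "max"]
    assert len(rows) == 3
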