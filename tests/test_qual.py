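"""Qualitative dynamics: targets, state-transition graphs, attractors."""

import itertools

import pytest

from conftest import brute_force_attractors
from sbmlkit.errors import CapacityError, ModelCompileError
from sbmlkit.fixtures import make_fixture
from sbmlkit.mathml import apply_op, num, sym
from sbmlkit.qual import (
    DefaultTerm,
    FunctionTerm,
    QualInput,
    QualOutput,
    QualSpecies,
    QualTransition,
    attractors_to_json,
    build_stg,
    find_attractors,
    stg_to_dot,
    stg_to_tsv,
    target_level,
)


class TestTargetLevel:
    def test_toggle_truth_table(self):
        m = make_fixture("toggle_qual").model
        state = {"A": 1, "B": 0}
        assert target_level(m, state, "A") == 1
        assert target_level(m, state, "B") == 0

    def test_constant_species_keeps_level(self):
        doc = make_fixture("toggle_qual")
        doc.model.qual.species[0].constant = True
        assert target_level(doc.model, {"A": 1, "B": 0}, "A") == 1

    def test_default_term_when_no_function_term_true(self):
        m = make_fixture("toggle_qual").model
        # A's only term is true when B == 0; with B=1 the default (0) applies
        assert target_level(m, {"A": 1, "B": 1}, "A") == 0

    def test_two_transitions_on_one_output_rejected(self):
        doc = make_fixture("toggle_qual")
        qm = doc.model.qual
        qm.transitions.append(
            QualTransition(
                id="dup",
                outputs=[QualOutput(qual_species="A")],
                default_term=DefaultTerm(result_level=0),
            )
        )
        with pytest.raises(ModelCompileError):
            target_level(doc.model, {"A": 0, "B": 0}, "A")

    def test_species_without_transition_keeps_level(self):
        doc = make_fixture("toggle_qual")
        doc.model.qual.transitions.pop(0)  # A now unregulated
        assert target_level(doc.model, {"A": 1, "B": 0}, "A") == 1


class TestBuildSTG:
    def test_toggle_synchronous_edges(self):
        m = make_fixture("toggle_qual").model
        stg = build_stg(m, "synchronous")
        assert len(stg.nodes) == 4
        edges = set(stg.edges)
        assert edges == {
            ((0, 0), (1, 1)), ((1, 1), (0, 0)),
            ((1, 0), (1, 0)), ((0, 1), (0, 1)),
        }

    def test_negative_feedback_synchronous_cycle(self):
        m = make_fixture("negfb_qual").model
        stg = build_stg(m, "synchronous")
        succ = dict(stg.edges)
        cycle = [(0, 0)]
        for _ in range(4):
            cycle.append(succ[cycle[-1]])
        assert cycle == [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]

    def test_synchronous_out_degree_exactly_one(self):
        for name in ("toggle_qual", "negfb_qual"):
            stg = build_stg(make_fixture(name).model, "synchronous")
            sources = [src for src, _ in stg.edges]
            assert sorted(sources) == sorted(stg.nodes)

    def test_total_relation_in_both_schemes(self):
        for name in ("toggle_qual", "negfb_qual"):
            for scheme in ("synchronous", "asynchronous"):
                stg = build_stg(make_fixture(name).model, scheme)
                assert {src for src, _ in stg.edges} == set(stg.nodes)

    def test_state_space_size(self):
        doc = make_fixture("toggle_qual")
        qm = doc.model.qual
        qm.species.clear()
        qm.transitions.clear()
        for i in range(10):
            qm.species.append(QualSpecies(id=f"X{i}", max_level=1))
        stg = build_stg(doc.model, "synchronous")
        assert len(stg.nodes) == 1024

    def test_capacity_error(self):
        doc = make_fixture("toggle_qual")
        with pytest.raises(CapacityError):
            build_stg(doc.model, "synchronous", cap=3)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            build_stg(make_fixture("toggle_qual").model, "chaotic")

    def test_multivalued_asynchronous_unitary_steps(self):
        """A species at 0 regulated toward level 2 moves one unit at a time."""
        doc = make_fixture("toggle_qual")
        qm = doc.model.qual
        qm.species.clear()
        qm.transitions.clear()
        qm.species.append(QualSpecies(id="A", max_level=2, initial_level=0))
        qm.transitions.append(
            QualTransition(
                id="up",
                outputs=[QualOutput(qual_species="A")],
                function_terms=[],
                default_term=DefaultTerm(result_level=2),
            )
        )
        stg = build_stg(doc.model, "asynchronous")
        assert ((0,), (1,)) in stg.edges
        assert ((0,), (2,)) not in stg.edges


class TestAttractors:
    def test_toggle_async_two_fixed_points(self):
        stg = build_stg(make_fixture("toggle_qual").model, "asynchronous")
        attractors = find_attractors(stg)
        assert [(a.states, a.fixed_point) for a in attractors] == [
            (((0, 1),), True), (((1, 0),), True)
        ]

    def test_negfb_sync_single_four_cycle(self):
        stg = build_stg(make_fixture("negfb_qual").model, "synchronous")
        attractors = find_attractors(stg)
        assert len(attractors) == 1
        assert len(attractors[0].states) == 4
        assert not attractors[0].fixed_point

    def test_all_constant_model_every_state_fixed(self):
        doc = make_fixture("toggle_qual")
        for qs in doc.model.qual.species:
            qs.constant = True
        stg = build_stg(doc.model, "synchronous")
        attractors = find_attractors(stg)
        assert len(attractors) == len(stg.nodes)
        assert all(a.fixed_point for a in attractors)

    def test_matches_brute_force_on_fixtures(self):
        for name in ("toggle_qual", "negfb_qual"):
            for scheme in ("synchronous", "asynchronous"):
                stg = build_stg(make_fixture(name).model, scheme)
                expected = brute_force_attractors(stg.nodes, stg.edges)
                got = [a.states for a in find_attractors(stg)]
                assert [tuple(sorted(s)) for s in got] == expected

    def test_every_state_reaches_an_attractor(self):
        """Attractor basins cover the whole state space."""
        import networkx as nx
        for name in ("toggle_qual", "negfb_qual"):
            for scheme in ("synchronous", "asynchronous"):
                stg = build_stg(make_fixture(name).model, scheme)
                g = nx.DiGraph(stg.edges)
                g.add_nodes_from(stg.nodes)
                attractor_states = {
                    s for a in find_attractors(stg) for s in a.states
                }
                for node in stg.nodes:
                    reach = nx.descendants(g, node) | {node}
                    assert reach & attractor_states


class TestExport:
    def test_dot(self):
        stg = build_stg(make_fixture("toggle_qual").model, "synchronous")
        dot = stg_to_dot(stg)
        assert dot.startswith("digraph")
        assert '"A1_B0"' in dot

    def test_tsv(self):
        stg = build_stg(make_fixture("toggle_qual").model, "synchronous")
        tsv = stg_to_tsv(stg)
        assert tsv.splitlines()[0] == "source\ttarget"
        assert len(tsv.strip().splitlines()) == 1 + len(stg.edges)

    def test_attractor_json(self):
        stg = build_stg(make_fixture("toggle_qual").model, "asynchronous")
        out = attractors_to_json(stg, find_attractors(stg))
        assert '"fixed_point": true' in out
        assert '"A"' in out and '"B"' in out
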