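"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately implemented without going through the
code paths they check: document comparison walks dataclass fields
recursively, the LP oracle enumerates polytope vertices by brute force,
and the logical-dynamics oracle recomputes successors from truth tables.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pytest

from sbmlkit.fixtures import FIXTURE_NAMES, make_fixture
from sbmlkit.model import Document


@pytest.fixture(params=FIXTURE_NAMES)
def fixture_doc(request) -> Document:
    return make_fixture(request.param)


# ---------------------------------------------------------------------------
# Deep semantic document comparison
# ---------------------------------------------------------------------------

# read-time bookkeeping, plus package declarations (the writer materializes
# implicit fbc/qual declarations; their round-trip is tested separately)
_IGNORED_FIELDS = {"read_diagnostics", "missing_attrs", "declared_packages"}


def _normalize(value):
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {
            f.name: _normalize(getattr(value, f.name))
            for f in dataclasses.fields(value)
            if f.name not in _IGNORED_FIELDS
        }
    if isinstance(value, (list, tuple)):
        return [_normalize(v) for v in value]
    if isinstance(value, dict):
        return {k: _normalize(v) for k, v in sorted(value.items())}
    return value


def docs_semantically_equal(a: Document, b: Document) -> bool:
    """Recursive field-by-field comparison, ignoring read-time bookkeeping."""
    return _normalize(a) == _normalize(b)


# ---------------------------------------------------------------------------
# Deliberately-broken corpus: one document per validator rule id
# ---------------------------------------------------------------------------


def make_broken(rule_id: str) -> Document:
    """A document constructed to trigger exactly one catalog rule."""
    from sbmlkit.io import CORE_NS_V2, read_sbml
    from sbmlkit.mathml import apply_op, num, sym
    from sbmlkit.model import Parameter, Rule, Species

    if rule_id == "E1001":
        doc = make_fixture("decay")
        doc.model.parameters.append(Parameter(id="k", value=1.0, constant=True))
        return doc
    if rule_id == "E1002":
        doc = make_fixture("decay")
        doc.model.species.append(
            Species(id="C", compartment="void", initial_amount=0.0,
                    has_only_substance_units=True)
        )
        return doc
    if rule_id == "E1003":
        doc = make_fixture("decay")
        doc.model.add_parameter("p", value=0.0, constant=False)
        doc.model.rules.append(Rule("assignment", "p", num(1)))
        doc.model.rules.append(Rule("assignment", "p", num(2)))
        return doc
    if rule_id == "E1004":
        doc = make_fixture("decay")
        doc.model.rules.append(Rule("assignment", "k", num(1)))
        return doc
    if rule_id == "E1005":
        doc = make_fixture("decay")
        doc.model.rules.append(Rule("rate", "A", num(-1)))
        return doc
    if rule_id == "E1006":
        xml = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="{CORE_NS_V2}" level="3" version="2">
  <model id="m">
    <listOfCompartments>
      <compartment id="c" size="1"/>
    </listOfCompartments>
  </model>
</sbml>
"""
        return read_sbml(xml)
    if rule_id == "E1007":
        doc = make_fixture("decay")
        doc.model.reactions[0].kinetic_law.math = apply_op(
            "times", sym("k_ghost"), sym("A"))
        return doc
    if rule_id == "E1008":
        xml = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="{CORE_NS_V2}" level="3" version="2">
  <model id="m">
    <listOfCompartments>
      <compartment constant="true" id="c" size="1"/>
    </listOfCompartments>
    <listOfRules>
      <algebraicRule>
        <math xmlns="http://www.w3.org/1998/Math/MathML">
          <cn>0</cn>
        </math>
      </algebraicRule>
    </listOfRules>
  </model>
</sbml>
"""
        return read_sbml(xml)
    if rule_id == "E1009":
        doc = make_fixture("decay")
        doc.model.parameters.append(
            Parameter(id="2bad", value=1.0, constant=True))
        return doc
    if rule_id == "W2001":
        doc = make_fixture("decay")
        m = doc.model
        m.species[0].substance_units = "mole"
        m.add_parameter("vol", value=1.0, constant=True, units="litre")
        m.reactions[0].kinetic_law.math = apply_op(
            "times", sym("k"), apply_op("plus", sym("A"), sym("vol")))
        return doc
    if rule_id == "W2002":
        doc = make_fixture("decay")
        m = doc.model
        m.add_compartment("c2", size=None, constant=True)
        m.add_species("X", "c2", initial_concentration=1.0,
                      has_only_substance_units=False)
        return doc
    if rule_id == "E3001":
        doc = make_fixture("chain_fbc")
        doc.model.parameter_by_id("cap_in").constant = False
        return doc
    if rule_id == "E3002":
        doc = make_fixture("chain_fbc")
        doc.model.fbc.active_objective = None
        return doc
    if rule_id == "E4001":
        doc = make_fixture("toggle_qual")
        doc.model.qual.species[0].initial_level = 2
        return doc
    if rule_id == "E4002":
        doc = make_fixture("toggle_qual")
        doc.model.qual.transitions[0].function_terms[0].result_level = 2
        return doc
    raise ValueError(f"no broken fixture for {rule_id!r}")


ALL_RULE_IDS = [
    "E1001", "E1002", "E1003", "E1004", "E1005", "E1006", "E1007", "E1008",
    "E1009", "W2001", "W2002", "E3001", "E3002", "E4001", "E4002",
]


# ---------------------------------------------------------------------------
# LP vertex-enumeration oracle
# ---------------------------------------------------------------------------


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray):
    """All vertices of {v : S v = 0, lb <= v <= ub} by basis enumeration.

    Exponential in the number of reactions; fine for <= 6.
    """
    n = len(lb)
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[1] != n:
        S = np.zeros((0, n))
    r = np.linalg.matrix_rank(S) if S.size else 0
    vertices = []
    if r == 0:
        for corner in itertools.product(*[(l, u) for l, u in zip(lb, ub)]):
            vertices.append(np.asarray(corner, dtype=float))
        return vertices
    for basic in itertools.combinations(range(n), r):
        B = S[:, basic]
        if np.linalg.matrix_rank(B) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for corner in itertools.product(
            *[(lb[j], ub[j]) for j in nonbasic]
        ):
            rhs = -S[:, nonbasic] @ np.asarray(corner) if nonbasic else \
                np.zeros(S.shape[0])
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v = np.empty(n)
            v[list(basic)] = sol
            for j, val in zip(nonbasic, corner):
                v[j] = val
            if (
                np.all(v >= lb - 1e-9)
                and np.all(v <= ub + 1e-9)
                and np.allclose(S @ v, 0.0, atol=1e-8)
            ):
                vertices.append(v)
    return vertices


def brute_force_lp(S, lb, ub, c, sense="max"):
    """Optimal objective by vertex enumeration; None when infeasible."""
    vertices = enumerate_vertices(np.asarray(S), np.asarray(lb, dtype=float),
                                  np.asarray(ub, dtype=float))
    if not vertices:
        return None
    values = [float(np.dot(c, v)) for v in vertices]
    return max(values) if sense == "max" else min(values)


def brute_force_fva(S, lb, ub, c, fraction, sense="max"):
    """FVA ranges via vertices of the polytope augmented with a slack
    variable s = c.v constrained to [fraction*opt, opt]."""
    opt = brute_force_lp(S, lb, ub, c, sense)
    assert opt is not None
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = len(lb)
    if S.shape[1] != n:
        S = np.zeros((0, n))
    aug = np.vstack([np.hstack([S, np.zeros((S.shape[0], 1))]),
                     np.hstack([np.asarray(c, dtype=float), [-1.0]])])
    if sense == "max":
        s_lo, s_hi = fraction * opt, opt
    else:
        s_lo, s_hi = opt, fraction * opt
    lb2 = np.append(np.asarray(lb, dtype=float), min(s_lo, s_hi))
    ub2 = np.append(np.asarray(ub, dtype=float), max(s_lo, s_hi))
    vertices = enumerate_vertices(aug, lb2, ub2)
    assert vertices
    arr = np.array(vertices)[:, :n]
    return arr.min(axis=0), arr.max(axis=0)


# ---------------------------------------------------------------------------
# Logical-dynamics brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_attractors(nodes, edges):
    """Terminal SCC enumeration by Tarjan-free brute force: a set of nodes
    is an attractor iff it is a minimal set closed under successors in
    which every node reaches every other."""
    succ: dict = {n: set() for n in nodes}
    for a, b in edges:
        succ[a].add(b)

    def reachable(start):
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in succ[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    reach = {n: reachable(n) for n in nodes}
    attractors = []
    seen_sets = set()
    for n in nodes:
        r = reach[n]
        # terminal SCC containing n: every node reachable from n can reach n
        if all(n in reach[m] for m in r):
            key = frozenset(r)
            if key not in seen_sets:
                seen_sets.add(key)
                attractors.append(tuple(sorted(r)))
    attractors.sort(key=lambda a: a[0])
    return attractors
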