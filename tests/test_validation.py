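"""Validator catalog and unit derivation."""

import numpy as np
import pytest

from conftest import ALL_RULE_IDS, make_broken
from sbmlkit.fixtures import make_fixture, random_network
from sbmlkit.mathml import apply_op, num, sym
from sbmlkit.model import Model
from sbmlkit.validation import (
    UNDECLARED,
    UnitVector,
    derive_units,
    diagnostics_to_json,
    diagnostics_to_text,
    validate_document,
)


class TestCatalog:
    @pytest.mark.parametrize("rule_id", ALL_RULE_IDS)
    def test_broken_fixture_triggers_its_rule(self, rule_id):
        doc = make_broken(rule_id)
        found = {d.rule_id for d in validate_document(doc)}
        assert rule_id in found

    def test_clean_fixtures_have_no_findings(self, fixture_doc):
        assert validate_document(fixture_doc) == []

    def test_validation_is_pure(self):
        doc = make_broken("E1001")
        assert validate_document(doc) == validate_document(doc)

    def test_duplicate_sid_message_names_the_sid(self):
        diags = validate_document(make_broken("E1001"))
        dup = [d for d in diags if d.rule_id == "E1001"]
        assert dup and "'k'" in dup[0].message

    def test_qual_level_bound(self):
        diags = validate_document(make_broken("E4001"))
        assert any(d.rule_id == "E4001" and "maxLevel" in d.message
                   for d in diags)

    def test_severities(self):
        for rule_id in ALL_RULE_IDS:
            for d in validate_document(make_broken(rule_id)):
                expected = "warning" if d.rule_id.startswith("W") else "error"
                assert d.severity == expected

    def test_text_and_json_rendering(self):
        diags = validate_document(make_broken("E1001"))
        text = diagnostics_to_text(diags)
        assert "ERROR E1001" in text
        assert '"rule_id": "E1001"' in diagnostics_to_json(diags)


def _unit_model() -> Model:
    m = Model(id="units")
    m.add_compartment("c", size=1.0, units="litre")
    m.add_species("A", "c", initial_amount=1.0,
                  has_only_substance_units=True, substance_units="mole")
    m.add_parameter("k", value=0.5, constant=True, units="per_second")
    m.add_parameter("V", value=2.0, constant=True, units="litre")
    m.add_parameter("x", value=1.0, constant=True)  # undeclared units
    from sbmlkit.model import Unit, UnitDefinition
    m.unit_definitions.append(
        UnitDefinition(id="per_second", units=[Unit("second", exponent=-1.0)])
    )
    return m


class TestDeriveUnits:
    def test_rate_law_units(self):
        m = _unit_model()
        out = derive_units(apply_op("times", sym("k"), sym("A")), m)
        assert isinstance(out, UnitVector)
        assert out.normalized() == {"mole": 1.0, "second": -1.0}

    def test_mismatched_plus_warns(self):
        m = _unit_model()
        warnings = []
        out = derive_units(apply_op("plus", sym("A"), sym("V")), m,
                           warnings=warnings)
        assert out == UNDECLARED
        assert warnings

    def test_undeclared_propagates_silently(self):
        m = _unit_model()
        warnings = []
        out = derive_units(apply_op("plus", sym("A"), sym("x")), m,
                           warnings=warnings)
        assert out == UNDECLARED
        assert warnings == []

    def test_dimensionless_power(self):
        m = _unit_model()
        out = derive_units(
            apply_op("power", num(2, units="dimensionless"), num(3)), m)
        assert isinstance(out, UnitVector) and out.is_dimensionless()

    def test_integer_power_scales_exponents(self):
        m = _unit_model()
        out = derive_units(apply_op("power", sym("V"), num(2)), m)
        assert out.normalized() == {"litre": 2.0}

    def test_division(self):
        m = _unit_model()
        out = derive_units(apply_op("divide", sym("A"), sym("V")), m)
        assert out.normalized() == {"mole": 1.0, "litre": -1.0}


def _oracle_units(node, env):
    """Independent exponent-map arithmetic for the random-expression check.

    Returns a plain dict of exponents, or None for 'unknown'.
    """
    from sbmlkit.mathml import Apply, Number, SymbolRef

    if isinstance(node, Number):
        return None if node.units_ref is None else {}
    if isinstance(node, SymbolRef):
        return env[node.sid]
    assert isinstance(node, Apply)
    args = [_oracle_units(a, env) for a in node.args]
    if node.op == "times":
        if any(a is None for a in args):
            return None
        out = {}
        for a in args:
            for k, v in a.items():
                out[k] = out.get(k, 0.0) + v
        return {k: v for k, v in out.items() if v != 0}
    if node.op == "divide":
        if any(a is None for a in args):
            return None
        out = dict(args[0])
        for k, v in args[1].items():
            out[k] = out.get(k, 0.0) - v
        return {k: v for k, v in out.items() if v != 0}
    if node.op == "plus":
        known = [a for a in args if a is not None]
        if len(known) < len(args):
            return None
        return known[0] if all(a == known[0] for a in known) else None
    raise AssertionError(node.op)


def test_unit_derivation_matches_random_oracle():
    """derive_units agrees with independent exponent bookkeeping on seeded
    random times/divide/plus expressions over dimensioned symbols."""
    rng = np.random.default_rng(123)
    m = Model(id="rand_units")
    m.add_compartment("c", size=1.0)
    kinds = ["mole", "litre", "second", "gram"]
    env = {}
    for i, kind in enumerate(kinds):
        pid = f"p{i}"
        m.add_parameter(pid, value=1.0, constant=True, units=kind)
        env[pid] = {kind: 1.0}
    syms = list(env)

    def random_expr(depth):
        if depth == 0 or rng.random() < 0.3:
            if rng.random() < 0.2:
                return num(float(rng.uniform(1, 2)))
            return sym(str(rng.choice(syms)))
        op = str(rng.choice(["times", "divide", "plus"]))
        n = 2 if op != "times" else int(rng.integers(2, 4))
        return apply_op(op, *[random_expr(depth - 1) for _ in range(n)])

    for _ in range(100):
        expr = random_expr(3)
        expected = _oracle_units(expr, env)
        got = derive_units(expr, m)
        if expected is None:
            assert got == UNDECLARED
        else:
            assert isinstance(got, UnitVector), expr
            assert got.normalized() == expected


def test_random_networks_are_validator_clean():
    for seed in range(5):
        assert validate_document(random_network(4, 6, seed=seed)) == []
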