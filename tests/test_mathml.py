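"""MathML subset: parsing, evaluation, analysis, inlining."""

import math

import numpy as np
import pytest

from sbmlkit.errors import (
    MathCycleError,
    MathEvalError,
    MathNameError,
    MathStructureError,
    MathTypeError,
    UnsupportedMathError,
)
from sbmlkit.mathml import (
    MATHML_NS,
    Apply,
    AvogadroSymbol,
    EvalEnv,
    Lambda,
    Number,
    Piecewise,
    SymbolRef,
    TimeSymbol,
    apply_op,
    compile_evaluator,
    evaluate,
    free_symbols,
    inline_function_definitions,
    mathml_to_string,
    num,
    parse_mathml,
    sym,
)


def wrap(inner: str) -> str:
    return f'<math xmlns="{MATHML_NS}">{inner}</math>'


class TestParsing:
    def test_times_apply(self):
        node = parse_mathml(wrap("<apply><times/><ci>k</ci><ci>A</ci></apply>"))
        assert node == Apply("times", (SymbolRef("k"), SymbolRef("A")))

    def test_time_csymbol(self):
        node = parse_mathml(wrap(
            '<csymbol definitionURL="http://www.sbml.org/sbml/symbols/time">'
            "t</csymbol>"
        ))
        assert node == TimeSymbol()

    def test_avogadro_csymbol(self):
        node = parse_mathml(wrap(
            '<csymbol definitionURL="http://www.sbml.org/sbml/symbols/avogadro">'
            "NA</csymbol>"
        ))
        assert node == AvogadroSymbol()

    def test_piecewise(self):
        node = parse_mathml(wrap(
            "<piecewise><piece><cn>0</cn>"
            "<apply><lt/><ci>x</ci><cn>1</cn></apply></piece>"
            "<otherwise><cn>1</cn></otherwise></piecewise>"
        ))
        assert isinstance(node, Piecewise)
        assert node.pieces == ((apply_op("lt", sym("x"), num(1)), num(0)),)
        assert node.otherwise == num(1)

    @pytest.mark.parametrize(
        "inner, value",
        [
            ('<cn type="integer">7</cn>', 7.0),
            ('<cn type="e-notation">1.5 <sep/> 2</cn>', 150.0),
            ('<cn type="rational">3 <sep/> 4</cn>', 0.75),
        ],
    )
    def test_cn_forms_fold_to_reals(self, inner, value):
        node = parse_mathml(wrap(inner))
        assert node == Number(value)

    def test_cn_units_attribute_recorded(self):
        node = parse_mathml(wrap(
            f'<cn xmlns:sbml="http://www.sbml.org/sbml/level3/version2/core" '
            f'sbml:units="mole">2</cn>'
        ))
        assert node == Number(2.0, units_ref="mole")

    @pytest.mark.parametrize(
        "inner",
        [
            "<apply><factorial/><cn>3</cn></apply>",
            "<apply><arcsin/><cn>0.5</cn></apply>",
            '<csymbol definitionURL="http://www.sbml.org/sbml/symbols/delay">'
            "d</csymbol>",
            '<csymbol definitionURL="http://www.sbml.org/sbml/symbols/rateOf">'
            "r</csymbol>",
        ],
    )
    def test_unsupported_constructs_rejected(self, inner):
        with pytest.raises(UnsupportedMathError):
            parse_mathml(wrap(inner))

    def test_malformed_xml(self):
        from sbmlkit.errors import SbmlParseError
        with pytest.raises(SbmlParseError):
            parse_mathml("<math><broken")

    def test_lambda(self):
        node = parse_mathml(wrap(
            "<lambda><bvar><ci>x</ci></bvar>"
            "<apply><times/><ci>x</ci><ci>k</ci></apply></lambda>"
        ))
        assert node == Lambda(("x",), apply_op("times", sym("x"), sym("k")))


class TestEvaluation:
    def test_arithmetic(self):
        assert evaluate(apply_op("plus", num(2), num(3)), EvalEnv()) == 5.0

    def test_piecewise_otherwise(self):
        pw = Piecewise(((apply_op("lt", sym("x"), num(1)), num(0)),), num(1))
        assert evaluate(pw, EvalEnv(bindings={"x": 2.0})) == 1.0
        assert evaluate(pw, EvalEnv(bindings={"x": 0.0})) == 0.0

    def test_piecewise_exhausted(self):
        pw = Piecewise(((apply_op("lt", sym("x"), num(1)), num(0)),), None)
        with pytest.raises(MathEvalError):
            evaluate(pw, EvalEnv(bindings={"x": 2.0}))

    def test_time_symbol(self):
        assert evaluate(TimeSymbol(), EvalEnv(time=4.0)) == 4.0

    def test_unbound_symbol(self):
        with pytest.raises(MathNameError):
            evaluate(sym("nope"), EvalEnv())

    def test_boolean_number_strictness(self):
        with pytest.raises(MathTypeError):
            evaluate(apply_op("plus", num(1), apply_op("lt", num(0), num(1))),
                     EvalEnv())
        with pytest.raises(MathTypeError):
            evaluate(apply_op("and", num(1), num(1)), EvalEnv())

    @pytest.mark.parametrize(
        "node, expected",
        [
            (apply_op("power", num(2), num(10)), 1024.0),
            (apply_op("root", num(2), num(9)), 3.0),
            (apply_op("log", num(10), num(1000)), 3.0),
            (apply_op("minus", num(4)), -4.0),
            (apply_op("xor", apply_op("lt", num(0), num(1)),
                      apply_op("lt", num(1), num(0))), True),
            (apply_op("leq", num(1), num(1), num(2)), True),
        ],
    )
    def test_operator_semantics(self, node, expected):
        assert evaluate(node, EvalEnv()) == expected

    def test_compiled_matches_interpreter(self):
        node = apply_op(
            "divide",
            apply_op("times", sym("Vmax"), sym("S")),
            apply_op("plus", sym("Km"), sym("S")),
        )
        env = EvalEnv(bindings={"Vmax": 1.0, "S": 10.0, "Km": 0.5})
        assert compile_evaluator(node)(env) == evaluate(node, env)

    def test_arity_checked_at_construction(self):
        with pytest.raises(MathStructureError):
            Apply("divide", (num(1),))
        with pytest.raises(MathStructureError):
            Apply("not", (num(1), num(2)))


class TestFreeSymbols:
    def test_simple(self):
        fs = free_symbols(apply_op("times", sym("k"), sym("A")))
        assert fs.names == {"k", "A"}
        assert not fs.uses_time

    def test_lambda_binds_parameters(self):
        lam = Lambda(("x",), apply_op("times", sym("x"), sym("k")))
        assert free_symbols(lam).names == {"k"}

    def test_number_has_none(self):
        fs = free_symbols(num(3))
        assert fs.names == frozenset()
        assert not fs.uses_time and not fs.uses_avogadro

    def test_time_flag(self):
        fs = free_symbols(apply_op("geq", TimeSymbol(), num(1)))
        assert fs.uses_time and fs.names == frozenset()


class TestInlining:
    def test_beta_reduction(self):
        defs = {"f": Lambda(("x", "y"), apply_op("times", sym("x"), sym("y")))}
        out = inline_function_definitions(Apply("f", (sym("k"), sym("A"))), defs)
        assert out == apply_op("times", sym("k"), sym("A"))

    def test_identity_without_calls(self):
        node = apply_op("plus", sym("a"), num(1))
        assert inline_function_definitions(node, {}) == node

    def test_recursion_detected(self):
        defs = {
            "f": Lambda(("x",), Apply("g", (sym("x"),))),
            "g": Lambda(("x",), Apply("f", (sym("x"),))),
        }
        with pytest.raises(MathCycleError):
            inline_function_definitions(Apply("f", (sym("a"),)), defs)

    def test_undefined_function(self):
        with pytest.raises(MathNameError):
            inline_function_definitions(Apply("h", (num(1),)), {})

    def test_arity_mismatch(self):
        defs = {"f": Lambda(("x", "y"), sym("x"))}
        with pytest.raises(MathStructureError):
            inline_function_definitions(Apply("f", (num(1),)), defs)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

_OPS_NUMERIC = ["plus", "times", "minus", "divide", "power", "abs", "sin",
                "cos", "exp"]


def _random_tree(rng, depth, symbols):
    """Random numeric expression tree, depth-bounded."""
    if depth == 0 or rng.random() < 0.3:
        if rng.random() < 0.5:
            return num(float(np.round(rng.uniform(0.5, 3.0), 3)))
        return sym(str(rng.choice(symbols)))
    op = str(rng.choice(_OPS_NUMERIC))
    if op in ("abs", "sin", "cos", "exp"):
        return apply_op(op, _random_tree(rng, depth - 1, symbols))
    if op == "power":
        return apply_op(op, _random_tree(rng, depth - 1, symbols),
                        num(float(rng.integers(1, 3))))
    if op in ("minus", "divide"):
        return apply_op(op, _random_tree(rng, depth - 1, symbols),
                        _random_tree(rng, depth - 1, symbols))
    n = int(rng.integers(2, 4))
    return apply_op(op, *[_random_tree(rng, depth - 1, symbols)
                          for _ in range(n)])


def _eval_with_call_semantics(node, env, defs):
    """Independent oracle: evaluate user-function calls by binding
    parameters in a child environment, without rewriting the tree."""
    from sbmlkit import mathml as M

    if isinstance(node, Apply) and node.op in defs:
        lam = defs[node.op]
        vals = [_eval_with_call_semantics(a, env, defs) for a in node.args]
        child = EvalEnv(bindings=dict(zip(lam.params, vals)), time=env.time)
        return _eval_with_call_semantics(lam.body, child, defs)
    if isinstance(node, Apply):
        vals = [_eval_with_call_semantics(a, env, defs) for a in node.args]
        return M._apply_op(node.op, vals)
    return evaluate(node, env)


def test_parse_serialize_parse_is_identity():
    """Round-tripping through the serializer preserves tree structure."""
    rng = np.random.default_rng(20240101)
    symbols = ["a", "b", "k"]
    for _ in range(200):
        tree = _random_tree(rng, 4, symbols)
        again = parse_mathml(mathml_to_string(tree))
        assert again == tree


def test_inlining_agrees_with_call_semantics():
    """Inlined evaluation equals direct call-semantics evaluation on
    randomized trees that invoke user-defined functions."""
    rng = np.random.default_rng(7)
    defs = {
        "f": Lambda(("x", "y"), apply_op("plus", sym("x"),
                                         apply_op("times", sym("y"), num(2)))),
        "g": Lambda(("x",), apply_op("times", sym("x"), sym("x"))),
    }
    env = EvalEnv(bindings={"a": 1.3, "b": 0.7, "k": 2.1})
    for _ in range(200):
        base = _random_tree(rng, 3, ["a", "b", "k"])
        arg2 = _random_tree(rng, 2, ["a", "b"])
        tree = Apply("f", (Apply("g", (base,)), arg2))
        inlined = inline_function_definitions(tree, defs)
        try:
            direct = _eval_with_call_semantics(tree, env, defs)
        except (OverflowError, ZeroDivisionError):
            continue
        via_inline = evaluate(inlined, env)
        if math.isfinite(direct):
            assert via_inline == pytest.approx(direct, rel=1e-12)


def test_piecewise_is_order_dependent():
    """With overlapping conditions, permuting pieces changes the result."""
    cond_a = apply_op("gt", sym("x"), num(0))
    cond_b = apply_op("gt", sym("x"), num(-1))
    pw1 = Piecewise(((cond_a, num(1)), (cond_b, num(2))), None)
    pw2 = Piecewise(((cond_b, num(2)), (cond_a, num(1))), None)
    env = EvalEnv(bindings={"x": 5.0})
    assert evaluate(pw1, env) == 1.0
    assert evaluate(pw2, env) == 2.0
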