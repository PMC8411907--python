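"""Content-MathML subset used inside SBML math containers.

The abstract syntax tree (:class:`MathNode` variants) is shared by kinetic
laws, rules, initial assignments, event triggers/assignments and qual
function terms.  The subset covers the operators commonly found in Level 3
models: arithmetic (``plus``, ``minus``, ``times``, ``divide``, ``power``,
``root``), elementary functions (``exp``, ``ln``, ``log``, ``abs``,
``floor``, ``ceiling``, ``sin``, ``cos``, ``tan``), relations (``eq``,
``neq``, ``lt``, ``leq``, ``gt``, ``geq``) and logic (``and``, ``or``,
``xor``, ``not``).  Anything outside the subset raises
:class:`~sbmlkit.errors.UnsupportedMathError` rather than being silently
misread; in particular the ``delay`` and ``rateOf`` csymbols are rejected
with a dedicated message.

Numbers are double-precision reals throughout (``<cn type="integer">``,
``"rational"`` and ``"e-notation"`` forms are folded into reals at parse
time).  Booleans and numbers are distinct value domains and never coerce
into each other.
"""

from __future__ import annotations

import math as _pymath
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Union

from lxml import etree

from .errors import (
    MathCycleError,
    MathEvalError,
    MathNameError,
    MathStructureError,
    MathTypeError,
    SbmlParseError,
    UnsupportedMathError,
)

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"
AVOGADRO_URL = "http://www.sbml.org/sbml/symbols/avogadro"
DELAY_URL = "http://www.sbml.org/sbml/symbols/delay"
RATEOF_URL = "http://www.sbml.org/sbml/symbols/rateOf"

AVOGADRO = 6.02214179e23

Value = Union[float, bool]

# ---------------------------------------------------------------------------
# AST node types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MathNode:
    """Base class for all expression nodes."""

    __slots__ = ()


@dataclass(frozen=True)
class Number(MathNode):
    value: float
    units_ref: str | None = None


@dataclass(frozen=True)
class SymbolRef(MathNode):
    sid: str


@dataclass(frozen=True)
class TimeSymbol(MathNode):
    pass


@dataclass(frozen=True)
class AvogadroSymbol(MathNode):
    pass


NAMED_CONSTS = {
    "pi": _pymath.pi,
    "exponentiale": _pymath.e,
    "true": True,
    "false": False,
    "notanumber": _pymath.nan,
    "infinity": _pymath.inf,
}


@dataclass(frozen=True)
class NamedConst(MathNode):
    name: str

    def __post_init__(self):
        if self.name not in NAMED_CONSTS:
            raise MathStructureError(f"unknown named constant {self.name!r}")


@dataclass(frozen=True)
class Apply(MathNode):
    op: str
    args: tuple[MathNode, ...]

    def __post_init__(self):
        object.__setattr__(self, "args", tuple(self.args))
        if self.op in _ARITY:
            lo, hi = _ARITY[self.op]
            n = len(self.args)
            if n < lo or (hi is not None and n > hi):
                raise MathStructureError(
                    f"operator {self.op!r} applied to {n} argument(s); "
                    f"expected between {lo} and {hi if hi is not None else 'n'}"
                )


@dataclass(frozen=True)
class Piecewise(MathNode):
    pieces: tuple[tuple[MathNode, MathNode], ...]  # (condition, value)
    otherwise: MathNode | None = None

    def __post_init__(self):
        object.__setattr__(self, "pieces", tuple(tuple(p) for p in self.pieces))


@dataclass(frozen=True)
class Lambda(MathNode):
    params: tuple[str, ...]
    body: MathNode

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(self.params))


# (min arity, max arity or None for n-ary).  `root` and `log` carry their
# degree/base as an explicit first argument (inserted with its default at
# parse time), so both are binary internally.
_ARITY: dict[str, tuple[int, int | None]] = {
    "plus": (1, None),
    "times": (1, None),
    "minus": (1, 2),
    "divide": (2, 2),
    "power": (2, 2),
    "root": (2, 2),
    "log": (2, 2),
    "exp": (1, 1),
    "ln": (1, 1),
    "abs": (1, 1),
    "floor": (1, 1),
    "ceiling": (1, 1),
    "sin": (1, 1),
    "cos": (1, 1),
    "tan": (1, 1),
    "eq": (2, None),
    "neq": (2, 2),
    "lt": (2, None),
    "leq": (2, None),
    "gt": (2, None),
    "geq": (2, None),
    "and": (1, None),
    "or": (1, None),
    "xor": (1, None),
    "not": (1, 1),
}

RELATIONAL_OPS = frozenset({"eq", "neq", "lt", "leq", "gt", "geq"})
LOGICAL_OPS = frozenset({"and", "or", "xor", "not"})
BOOLEAN_RESULT_OPS = RELATIONAL_OPS | LOGICAL_OPS


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _q(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def _localname(el) -> str:
    qname = etree.QName(el)
    if qname.namespace != MATHML_NS:
        raise UnsupportedMathError(
            f"element {el.tag!r} is not in the MathML namespace"
        )
    return qname.localname


def parse_mathml(fragment: bytes | str) -> MathNode:
    """Parse a ``<math>`` element (or serialized fragment) into an AST.

    Accepts bytes/str XML text or an already-parsed lxml element.
    """
    if isinstance(fragment, (bytes, str)):
        if isinstance(fragment, str):
            fragment = fragment.encode("utf-8")
        try:
            el = etree.fromstring(fragment)
        except etree.XMLSyntaxError as exc:
            raise SbmlParseError(f"malformed MathML: {exc}") from exc
    else:
        el = fragment
    if _localname(el) != "math":
        raise UnsupportedMathError(
            f"expected a <math> root element, got <{_localname(el)}>"
        )
    children = _element_children(el)
    if len(children) != 1:
        raise MathStructureError(
            f"<math> must contain exactly one expression, found {len(children)}"
        )
    return parse_mathml_element(children[0])


def _element_children(el) -> list:
    return [c for c in el if isinstance(c.tag, str)]


def _parse_cn(el) -> Number:
    ctype = el.get("type", "real")
    units = None
    for key, val in el.attrib.items():
        if key == "units" or key.endswith("}units"):
            units = val
    text = (el.text or "").strip()
    if ctype in ("real", "integer", "double"):
        try:
            value = float(text)
        except ValueError as exc:
            raise MathStructureError(f"invalid <cn> content {text!r}") from exc
    elif ctype in ("e-notation", "rational"):
        sep = el.findall(_q("sep"))
        if len(sep) != 1:
            raise MathStructureError(f"<cn type={ctype!r}> needs one <sep/>")
        first = text
        second = (sep[0].tail or "").strip()
        try:
            a, b = float(first), float(second)
        except ValueError as exc:
            raise MathStructureError(f"invalid <cn> content") from exc
        if ctype == "e-notation":
            value = a * 10.0 ** b
        else:
            if b == 0:
                raise MathStructureError("rational <cn> with zero denominator")
            value = a / b
    else:
        raise UnsupportedMathError(f"unsupported <cn> type {ctype!r}")
    return Number(value, units_ref=units)


def _parse_csymbol(el) -> MathNode:
    url = el.get("definitionURL", "")
    if url == TIME_URL:
        return TimeSymbol()
    if url == AVOGADRO_URL:
        return AvogadroSymbol()
    if url == DELAY_URL:
        raise UnsupportedMathError(
            "the delay csymbol is not supported by this toolkit"
        )
    if url == RATEOF_URL:
        raise UnsupportedMathError(
            "the rateOf csymbol is not supported by this toolkit"
        )
    raise UnsupportedMathError(f"unsupported csymbol definitionURL {url!r}")


def parse_mathml_element(el) -> MathNode:
    """Parse one MathML content element into a :class:`MathNode`."""
    name = _localname(el)
    if name == "cn":
        return _parse_cn(el)
    if name == "ci":
        sid = (el.text or "").strip()
        if not sid:
            raise MathStructureError("empty <ci> element")
        return SymbolRef(sid)
    if name == "csymbol":
        return _parse_csymbol(el)
    if name in NAMED_CONSTS:
        return NamedConst(name)
    if name == "apply":
        return _parse_apply(el)
    if name == "piecewise":
        return _parse_piecewise(el)
    if name == "lambda":
        return _parse_lambda(el)
    raise UnsupportedMathError(f"unsupported MathML element <{name}>")


def _parse_apply(el) -> Apply:
    children = _element_children(el)
    if not children:
        raise MathStructureError("empty <apply>")
    head, rest = children[0], children[1:]
    head_name = _localname(head)
    if head_name == "ci":
        # user-defined function call
        fname = (head.text or "").strip()
        return Apply(fname, tuple(parse_mathml_element(c) for c in rest))
    if head_name == "csymbol":
        _parse_csymbol(head)  # raises for delay/rateOf; time/avogadro not callable
        raise UnsupportedMathError("csymbol cannot be applied as a function")
    op = head_name
    if op not in _ARITY:
        raise UnsupportedMathError(f"unsupported MathML operator <{op}>")
    qualifier = None
    args: list[MathNode] = []
    for c in rest:
        cname = _localname(c)
        if cname in ("degree", "logbase"):
            inner = _element_children(c)
            if len(inner) != 1:
                raise MathStructureError(f"<{cname}> must wrap one expression")
            qualifier = parse_mathml_element(inner[0])
        else:
            args.append(parse_mathml_element(c))
    if op == "root":
        args.insert(0, qualifier if qualifier is not None else Number(2.0))
    elif op == "log":
        args.insert(0, qualifier if qualifier is not None else Number(10.0))
    elif qualifier is not None:
        raise MathStructureError(f"qualifier not allowed under <{op}>")
    return Apply(op, tuple(args))


def _parse_piecewise(el) -> Piecewise:
    pieces: list[tuple[MathNode, MathNode]] = []
    otherwise: MathNode | None = None
    for c in _element_children(el):
        cname = _localname(c)
        inner = _element_children(c)
        if cname == "piece":
            if len(inner) != 2:
                raise MathStructureError("<piece> must contain value and condition")
            value = parse_mathml_element(inner[0])
            cond = parse_mathml_element(inner[1])
            pieces.append((cond, value))
        elif cname == "otherwise":
            if len(inner) != 1:
                raise MathStructureError("<otherwise> must contain one expression")
            otherwise = parse_mathml_element(inner[0])
        else:
            raise MathStructureError(f"unexpected <{cname}> inside <piecewise>")
    return Piecewise(tuple(pieces), otherwise)


def _parse_lambda(el) -> Lambda:
    params: list[str] = []
    body: MathNode | None = None
    for c in _element_children(el):
        cname = _localname(c)
        if cname == "bvar":
            inner = _element_children(c)
            if len(inner) != 1 or _localname(inner[0]) != "ci":
                raise MathStructureError("<bvar> must contain one <ci>")
            params.append((inner[0].text or "").strip())
        else:
            if body is not None:
                raise MathStructureError("<lambda> with more than one body")
            body = parse_mathml_element(c)
    if body is None:
        raise MathStructureError("<lambda> without a body")
    return Lambda(tuple(params), body)


# ---------------------------------------------------------------------------
# Serialization (canonical form used by the SBML writer)
# ---------------------------------------------------------------------------


def format_number(v: float) -> str:
    """Shortest representation that reparses to the identical double."""
    if v != v:
        return "nan"
    if v == _pymath.inf:
        return "inf"
    if v == -_pymath.inf:
        return "-inf"
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def mathml_lines(node: MathNode, indent: int = 0, sbml_prefix: str = "sbml") -> list[str]:
    """Serialize a node to indented content-MathML lines (without <math>)."""
    pad = "  " * indent
    if isinstance(node, Number):
        attrs = ""
        text = format_number(node.value)
        if node.units_ref is not None:
            attrs = f' {sbml_prefix}:units="{node.units_ref}"'
        if "e" in text or "E" in text:
            mant, _, expo = text.partition("e")
            return [
                f'{pad}<cn{attrs} type="e-notation">{mant} <sep/> {int(expo)}</cn>'
            ]
        return [f"{pad}<cn{attrs}>{text}</cn>"]
    if isinstance(node, SymbolRef):
        return [f"{pad}<ci>{node.sid}</ci>"]
    if isinstance(node, TimeSymbol):
        return [f'{pad}<csymbol cd="sbml" definitionURL="{TIME_URL}">time</csymbol>']
    if isinstance(node, AvogadroSymbol):
        return [
            f'{pad}<csymbol cd="sbml" definitionURL="{AVOGADRO_URL}">avogadro</csymbol>'
        ]
    if isinstance(node, NamedConst):
        return [f"{pad}<{node.name}/>"]
    if isinstance(node, Apply):
        return _apply_lines(node, indent, sbml_prefix)
    if isinstance(node, Piecewise):
        lines = [f"{pad}<piecewise>"]
        for cond, value in node.pieces:
            lines.append(f"{pad}  <piece>")
            lines.extend(mathml_lines(value, indent + 2, sbml_prefix))
            lines.extend(mathml_lines(cond, indent + 2, sbml_prefix))
            lines.append(f"{pad}  </piece>")
        if node.otherwise is not None:
            lines.append(f"{pad}  <otherwise>")
            lines.extend(mathml_lines(node.otherwise, indent + 2, sbml_prefix))
            lines.append(f"{pad}  </otherwise>")
        lines.append(f"{pad}</piecewise>")
        return lines
    if isinstance(node, Lambda):
        lines = [f"{pad}<lambda>"]
        for p in node.params:
            lines.append(f"{pad}  <bvar>")
            lines.append(f"{pad}    <ci>{p}</ci>")
            lines.append(f"{pad}  </bvar>")
        lines.extend(mathml_lines(node.body, indent + 1, sbml_prefix))
        lines.append(f"{pad}</lambda>")
        return lines
    raise MathStructureError(f"cannot serialize node {node!r}")


def _apply_lines(node: Apply, indent: int, sbml_prefix: str) -> list[str]:
    pad = "  " * indent
    lines = [f"{pad}<apply>"]
    args = list(node.args)
    if node.op in _ARITY:
        lines.append(f"{pad}  <{node.op}/>")
        if node.op == "root":
            lines.append(f"{pad}  <degree>")
            lines.extend(mathml_lines(args[0], indent + 2, sbml_prefix))
            lines.append(f"{pad}  </degree>")
            args = args[1:]
        elif node.op == "log":
            lines.append(f"{pad}  <logbase>")
            lines.extend(mathml_lines(args[0], indent + 2, sbml_prefix))
            lines.append(f"{pad}  </logbase>")
            args = args[1:]
    else:
        lines.append(f"{pad}  <ci>{node.op}</ci>")
    for a in args:
        lines.extend(mathml_lines(a, indent + 1, sbml_prefix))
    lines.append(f"{pad}</apply>")
    return lines


def mathml_to_string(node: MathNode, indent: int = 0) -> str:
    """Serialize a node to a full ``<math>`` fragment."""
    pad = "  " * indent
    lines = [f'{pad}<math xmlns="{MATHML_NS}">']
    lines.extend(mathml_lines(node, indent + 1))
    lines.append(f"{pad}</math>")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalEnv:
    """Bindings for evaluating an expression tree.

    ``bindings`` maps SIds to reals or booleans; ``time`` is the value the
    time csymbol evaluates to; the Avogadro csymbol is a fixed constant.
    """

    bindings: dict[str, Value] = field(default_factory=dict)
    time: float = 0.0
    avogadro: float = AVOGADRO


def _need_num(v: Value, ctx: str) -> float:
    if isinstance(v, bool):
        raise MathTypeError(f"boolean value where a number is required in {ctx}")
    return v


def _need_bool(v: Value, ctx: str) -> bool:
    if not isinstance(v, bool):
        raise MathTypeError(f"numeric value where a boolean is required in {ctx}")
    return v


def _apply_op(op: str, vals: list[Value]) -> Value:
    if op == "plus":
        return _pymath.fsum(_need_num(v, "plus") for v in vals)
    if op == "times":
        out = 1.0
        for v in vals:
            out *= _need_num(v, "times")
        return out
    if op == "minus":
        if len(vals) == 1:
            return -_need_num(vals[0], "minus")
        return _need_num(vals[0], "minus") - _need_num(vals[1], "minus")
    if op == "divide":
        return _need_num(vals[0], "divide") / _need_num(vals[1], "divide")
    if op == "power":
        return float(_need_num(vals[0], "power") ** _need_num(vals[1], "power"))
    if op == "root":
        degree = _need_num(vals[0], "root degree")
        return float(_need_num(vals[1], "root") ** (1.0 / degree))
    if op == "log":
        base = _need_num(vals[0], "logbase")
        x = _need_num(vals[1], "log")
        if base == 10.0:
            return _pymath.log10(x)
        if base == 2.0:
            return _pymath.log2(x)
        return _pymath.log(x) / _pymath.log(base)
    if op == "exp":
        return _pymath.exp(_need_num(vals[0], "exp"))
    if op == "ln":
        return _pymath.log(_need_num(vals[0], "ln"))
    if op == "abs":
        return abs(_need_num(vals[0], "abs"))
    if op == "floor":
        return float(_pymath.floor(_need_num(vals[0], "floor")))
    if op == "ceiling":
        return float(_pymath.ceil(_need_num(vals[0], "ceiling")))
    if op == "sin":
        return _pymath.sin(_need_num(vals[0], "sin"))
    if op == "cos":
        return _pymath.cos(_need_num(vals[0], "cos"))
    if op == "tan":
        return _pymath.tan(_need_num(vals[0], "tan"))
    if op in ("eq", "neq"):
        kinds = {isinstance(v, bool) for v in vals}
        if len(kinds) > 1:
            raise MathTypeError(f"{op} comparing boolean with number")
        if op == "eq":
            return all(vals[i] == vals[i + 1] for i in range(len(vals) - 1))
        return vals[0] != vals[1]
    if op in ("lt", "leq", "gt", "geq"):
        nums = [_need_num(v, op) for v in vals]
        cmp = {
            "lt": lambda a, b: a < b,
            "leq": lambda a, b: a <= b,
            "gt": lambda a, b: a > b,
            "geq": lambda a, b: a >= b,
        }[op]
        return all(cmp(nums[i], nums[i + 1]) for i in range(len(nums) - 1))
    if op == "and":
        return all(_need_bool(v, "and") for v in vals)
    if op == "or":
        return any(_need_bool(v, "or") for v in vals)
    if op == "xor":
        out = False
        for v in vals:
            out ^= _need_bool(v, "xor")
        return out
    if op == "not":
        return not _need_bool(vals[0], "not")
    raise MathNameError(f"undefined function or operator {op!r}")


def evaluate(node: MathNode, env: EvalEnv) -> Value:
    """Evaluate an expression tree under the given environment.

    Piecewise returns the value of the first piece whose condition is true,
    falling back to ``otherwise``; no true piece and no otherwise is an
    evaluation error.  Lambda nodes cannot be evaluated directly (inline
    function definitions first).
    """
    if isinstance(node, Number):
        return node.value
    if isinstance(node, SymbolRef):
        try:
            return env.bindings[node.sid]
        except KeyError:
            raise MathNameError(f"unbound symbol {node.sid!r}") from None
    if isinstance(node, TimeSymbol):
        return env.time
    if isinstance(node, AvogadroSymbol):
        return env.avogadro
    if isinstance(node, NamedConst):
        return NAMED_CONSTS[node.name]
    if isinstance(node, Apply):
        return _apply_op(node.op, [evaluate(a, env) for a in node.args])
    if isinstance(node, Piecewise):
        for cond, value in node.pieces:
            if _need_bool(evaluate(cond, env), "piecewise condition"):
                return evaluate(value, env)
        if node.otherwise is not None:
            return evaluate(node.otherwise, env)
        raise MathEvalError("piecewise: no condition true and no otherwise branch")
    if isinstance(node, Lambda):
        raise MathStructureError("cannot evaluate a bare lambda")
    raise MathStructureError(f"cannot evaluate node {node!r}")


def compile_evaluator(node: MathNode) -> Callable[[EvalEnv], Value]:
    """Compile a tree into a closure; dispatch is resolved once, not per call.

    Used in simulation hot loops; semantically identical to :func:`evaluate`.
    """
    if isinstance(node, Number):
        v = node.value
        return lambda env: v
    if isinstance(node, SymbolRef):
        sid = node.sid
        def _sym(env, _sid=sid):
            try:
                return env.bindings[_sid]
            except KeyError:
                raise MathNameError(f"unbound symbol {_sid!r}") from None
        return _sym
    if isinstance(node, TimeSymbol):
        return lambda env: env.time
    if isinstance(node, AvogadroSymbol):
        return lambda env: env.avogadro
    if isinstance(node, NamedConst):
        v = NAMED_CONSTS[node.name]
        return lambda env: v
    if isinstance(node, Apply):
        arg_fns = [compile_evaluator(a) for a in node.args]
        op = node.op
        return lambda env: _apply_op(op, [f(env) for f in arg_fns])
    if isinstance(node, Piecewise):
        piece_fns = [
            (compile_evaluator(c), compile_evaluator(v)) for c, v in node.pieces
        ]
        other_fn = (
            compile_evaluator(node.otherwise) if node.otherwise is not None else None
        )
        def _pw(env):
            for cf, vf in piece_fns:
                if _need_bool(cf(env), "piecewise condition"):
                    return vf(env)
            if other_fn is not None:
                return other_fn(env)
            raise MathEvalError("piecewise: no condition true and no otherwise branch")
        return _pw
    raise MathStructureError(f"cannot compile node {node!r}")


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FreeSymbols:
    names: frozenset[str]
    uses_time: bool
    uses_avogadro: bool


def free_symbols(node: MathNode) -> FreeSymbols:
    """Collect free SIds; lambda parameters are bound and excluded.

    The time and Avogadro csymbols are reported via flags, not in the set.
    """
    names: set[str] = set()
    flags = {"time": False, "avogadro": False}

    def walk(n: MathNode, bound: frozenset[str]):
        if isinstance(n, SymbolRef):
            if n.sid not in bound:
                names.add(n.sid)
        elif isinstance(n, TimeSymbol):
            flags["time"] = True
        elif isinstance(n, AvogadroSymbol):
            flags["avogadro"] = True
        elif isinstance(n, Apply):
            if n.op not in _ARITY and n.op not in bound:
                names.add(n.op)  # user-function reference
            for a in n.args:
                walk(a, bound)
        elif isinstance(n, Piecewise):
            for cond, value in n.pieces:
                walk(cond, bound)
                walk(value, bound)
            if n.otherwise is not None:
                walk(n.otherwise, bound)
        elif isinstance(n, Lambda):
            walk(n.body, bound | frozenset(n.params))

    walk(node, frozenset())
    return FreeSymbols(frozenset(names), flags["time"], flags["avogadro"])


def _substitute(node: MathNode, mapping: Mapping[str, MathNode]) -> MathNode:
    if isinstance(node, SymbolRef):
        return mapping.get(node.sid, node)
    if isinstance(node, Apply):
        return Apply(node.op, tuple(_substitute(a, mapping) for a in node.args))
    if isinstance(node, Piecewise):
        return Piecewise(
            tuple(
                (_substitute(c, mapping), _substitute(v, mapping))
                for c, v in node.pieces
            ),
            _substitute(node.otherwise, mapping) if node.otherwise else None,
        )
    if isinstance(node, Lambda):
        inner = {k: v for k, v in mapping.items() if k not in node.params}
        return Lambda(node.params, _substitute(node.body, inner))
    return node


def inline_function_definitions(
    node: MathNode, defs: Mapping[str, Lambda]
) -> MathNode:
    """Beta-reduce all user-function applications using ``defs``.

    Substitution of arguments for parameters is simultaneous and capture-free
    (nested lambdas shadow their parameters).  Mutually recursive definitions
    are detected and rejected.
    """

    def expand(n: MathNode, active: frozenset[str]) -> MathNode:
        if isinstance(n, Apply):
            args = tuple(expand(a, active) for a in n.args)
            if n.op in _ARITY:
                return Apply(n.op, args)
            if n.op not in defs:
                raise MathNameError(f"undefined function {n.op!r}")
            if n.op in active:
                raise MathCycleError(
                    f"recursive function definition involving {n.op!r}"
                )
            lam = defs[n.op]
            if len(lam.params) != len(args):
                raise MathStructureError(
                    f"function {n.op!r} expects {len(lam.params)} argument(s), "
                    f"got {len(args)}"
                )
            body = expand(lam.body, active | {n.op})
            return _substitute(body, dict(zip(lam.params, args)))
        if isinstance(n, Piecewise):
            return Piecewise(
                tuple(
                    (expand(c, active), expand(v, active)) for c, v in n.pieces
                ),
                expand(n.otherwise, active) if n.otherwise else None,
            )
        if isinstance(n, Lambda):
            return Lambda(n.params, expand(n.body, active))
        return n

    return expand(node, frozenset())


# ---------------------------------------------------------------------------
# Infix rendering (diagnostics only)
# ---------------------------------------------------------------------------

_INFIX = {
    "plus": " + ",
    "minus": " - ",
    "times": " * ",
    "divide": " / ",
    "eq": " == ",
    "neq": " != ",
    "lt": " < ",
    "leq": " <= ",
    "gt": " > ",
    "geq": " >= ",
    "and": " && ",
    "or": " || ",
}


def to_infix(node: MathNode) -> str:
    """Human-readable rendering for messages; not meant to be reparsed."""
    if isinstance(node, Number):
        return format_number(node.value)
    if isinstance(node, SymbolRef):
        return node.sid
    if isinstance(node, TimeSymbol):
        return "time"
    if isinstance(node, AvogadroSymbol):
        return "avogadro"
    if isinstance(node, NamedConst):
        return node.name
    if isinstance(node, Apply):
        if node.op == "power":
            return f"({to_infix(node.args[0])}^{to_infix(node.args[1])})"
        if node.op in _INFIX and len(node.args) >= 2:
            return "(" + _INFIX[node.op].join(to_infix(a) for a in node.args) + ")"
        if node.op == "minus" and len(node.args) == 1:
            return f"(-{to_infix(node.args[0])})"
        return f"{node.op}({', '.join(to_infix(a) for a in node.args)})"
    if isinstance(node, Piecewise):
        parts = [f"{to_infix(v)} if {to_infix(c)}" for c, v in node.pieces]
        if node.otherwise is not None:
            parts.append(f"{to_infix(node.otherwise)} otherwise")
        return "piecewise(" + "; ".join(parts) + ")"
    if isinstance(node, Lambda):
        return f"lambda({', '.join(node.params)}: {to_infix(node.body)})"
    return repr(node)


def num(value: float, units: str | None = None) -> Number:
    """Convenience constructor used by fixtures and tests."""
    return Number(float(value), units_ref=units)


def sym(sid: str) -> SymbolRef:
    return SymbolRef(sid)


def apply_op(op: str, *args: MathNode) -> Apply:
    return Apply(op, tuple(args))
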