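"""Structural, referential and unit-consistency validation.

Findings are data, not exceptions: :func:`validate_document` returns an
ordered list of :class:`Diagnostic` (document order, then rule id).  The
rule catalog is this toolkit's own stable numbering:

======  ========  ====================================================
rule    severity  meaning
======  ========  ====================================================
E1001   error     duplicate SId
E1002   error     unresolved SIdRef
E1003   error     more than one rule / initial assignment per symbol
E1004   error     rule or event assignment targets a constant element
E1005   error     non-boundary species with a rate rule also in a reaction
E1006   error     missing required core attribute
E1007   error     math references an undefined symbol or function
E1008   error     unsupported math or structural construct
E1009   error     invalid SId syntax
W2001   warning   unit inconsistency inside a math expression
W2002   warning   unset compartment size with concentration-based species
E3001   error     fbc flux-bound parameter missing/non-constant/unresolved
E3002   error     fbc model without an active objective
E4001   error     qual initialLevel above maxLevel
E4002   error     qual function-term result level above output maxLevel
======  ========  ====================================================

Unit checks are warnings, never errors: units are verification aids and
real-world models frequently omit them.  Symbols without declared units
propagate "undeclared" silently; only a genuine mismatch between two
*declared* unit vectors warns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

from . import mathml as M
from .errors import MathCycleError, MathNameError, MathStructureError
from .mathml import (
    Apply,
    AvogadroSymbol,
    FreeSymbols,
    Lambda,
    MathNode,
    NamedConst,
    Number,
    Piecewise,
    SymbolRef,
    TimeSymbol,
    free_symbols,
    inline_function_definitions,
)
from .model import (
    BASE_UNIT_KINDS,
    Document,
    Model,
    is_valid_sid,
)

SEVERITIES = ("error", "warning")

#: sentinel result of :func:`derive_units` for unknown dimensions
UNDECLARED = "undeclared"


@dataclass
class Diagnostic:
    rule_id: str
    severity: str
    path: str
    message: str

    def render(self) -> str:
        return f"{self.severity.upper()} {self.rule_id} {self.path}: {self.message}"


def diagnostics_to_text(diags: list[Diagnostic]) -> str:
    return "\n".join(d.render() for d in diags) + ("\n" if diags else "")


def diagnostics_to_json(diags: list[Diagnostic]) -> str:
    return json.dumps(
        [
            {"rule_id": d.rule_id, "severity": d.severity, "path": d.path,
             "message": d.message}
            for d in diags
        ],
        indent=2,
    ) + "\n"


# ---------------------------------------------------------------------------
# Unit algebra
# ---------------------------------------------------------------------------


@dataclass
class UnitVector:
    """Exponent map over SBML base-unit kinds plus a scalar factor."""

    exponents: dict[str, float] = field(default_factory=dict)
    factor: float = 1.0

    def normalized(self) -> dict[str, float]:
        return {k: v for k, v in self.exponents.items() if v != 0.0}

    def same_dimensions(self, other: "UnitVector") -> bool:
        if self.normalized() != other.normalized():
            return False
        a, b = self.factor, other.factor
        return abs(a - b) <= 1e-9 * max(abs(a), abs(b), 1.0)

    def times(self, other: "UnitVector") -> "UnitVector":
        exps = dict(self.exponents)
        for k, v in other.exponents.items():
            exps[k] = exps.get(k, 0.0) + v
        return UnitVector(exps, self.factor * other.factor)

    def divide(self, other: "UnitVector") -> "UnitVector":
        exps = dict(self.exponents)
        for k, v in other.exponents.items():
            exps[k] = exps.get(k, 0.0) - v
        return UnitVector(exps, self.factor / other.factor)

    def power(self, n: float) -> "UnitVector":
        return UnitVector(
            {k: v * n for k, v in self.exponents.items()}, self.factor ** n
        )

    def is_dimensionless(self) -> bool:
        return not self.normalized() and abs(self.factor - 1.0) <= 1e-9


DIMENSIONLESS = UnitVector()

UnitResult = Union[UnitVector, str]  # UnitVector or UNDECLARED


def resolve_unit_ref(model: Model, unit_sid: Optional[str]) -> UnitResult:
    """Resolve a unit SId: a base-unit kind, or a unit definition."""
    if unit_sid is None:
        return UNDECLARED
    if unit_sid == "dimensionless":
        return UnitVector()
    if unit_sid in BASE_UNIT_KINDS:
        return UnitVector({unit_sid: 1.0})
    ud = model.unit_definition_by_id(unit_sid)
    if ud is None:
        return UNDECLARED
    out = UnitVector()
    for u in ud.units:
        base = UnitVector() if u.kind == "dimensionless" else UnitVector({u.kind: 1.0})
        contrib = base.power(u.exponent)
        contrib.factor *= (u.multiplier * 10.0 ** u.scale) ** u.exponent
        out = out.times(contrib)
    return out


def _symbol_units(model: Model, scope: Optional[str]) -> dict[str, UnitResult]:
    env: dict[str, UnitResult] = {}
    for c in model.compartments:
        env[c.id] = resolve_unit_ref(model, c.units)
    for p in model.parameters:
        env[p.id] = resolve_unit_ref(model, p.units)
    for s in model.species:
        substance = resolve_unit_ref(model, s.substance_units)
        if s.has_only_substance_units:
            env[s.id] = substance
        else:
            comp_units = UNDECLARED
            for c in model.compartments:
                if c.id == s.compartment:
                    comp_units = resolve_unit_ref(model, c.units)
            if substance is UNDECLARED or comp_units is UNDECLARED:
                env[s.id] = UNDECLARED
            else:
                env[s.id] = substance.divide(comp_units)
    if scope is not None:
        for r in model.reactions:
            if r.id == scope and r.kinetic_law is not None:
                for lp in r.kinetic_law.local_parameters:
                    env[lp.id] = resolve_unit_ref(model, lp.units)
    return env


def derive_units(node: MathNode, model: Model,
                 scope: Optional[str] = None,
                 warnings: Optional[list[str]] = None) -> UnitResult:
    """Dimensional analysis of an expression over the model's declared units.

    Returns a :class:`UnitVector` or the string ``"undeclared"``.  Genuine
    mismatches (e.g. adding moles to litres) append a message to
    ``warnings``; undeclared operands propagate silently.  The node must not
    contain user-function applications — inline them first.
    """
    if warnings is None:
        warnings = []
    env = _symbol_units(model, scope)
    time_units = resolve_unit_ref(model, model.time_units)
    return _derive(node, model, env, time_units, warnings)


def _derive(node: MathNode, model: Model, env, time_units, warnings) -> UnitResult:
    if isinstance(node, Number):
        return resolve_unit_ref(model, node.units_ref)
    if isinstance(node, SymbolRef):
        return env.get(node.sid, UNDECLARED)
    if isinstance(node, TimeSymbol):
        return time_units
    if isinstance(node, AvogadroSymbol):
        return UNDECLARED
    if isinstance(node, NamedConst):
        return UnitVector()
    if isinstance(node, Piecewise):
        vals = [_derive(v, model, env, time_units, warnings)
                for _, v in node.pieces]
        for cond, _ in node.pieces:
            _derive(cond, model, env, time_units, warnings)
        if node.otherwise is not None:
            vals.append(_derive(node.otherwise, model, env, time_units, warnings))
        return _require_identical(vals, "piecewise branches", warnings)
    if isinstance(node, Apply):
        return _derive_apply(node, model, env, time_units, warnings)
    if isinstance(node, Lambda):
        raise MathStructureError("inline function definitions before unit analysis")
    return UNDECLARED


def _require_identical(vals, ctx, warnings) -> UnitResult:
    declared = [v for v in vals if v is not UNDECLARED]
    if len(declared) < len(vals):
        return UNDECLARED
    if not declared:
        return UNDECLARED
    first = declared[0]
    for other in declared[1:]:
        if not first.same_dimensions(other):
            warnings.append(
                f"unit mismatch in {ctx}: {_unit_str(first)} vs {_unit_str(other)}"
            )
            return UNDECLARED
    return first


def _unit_str(u: UnitVector) -> str:
    parts = [f"{k}^{v:g}" if v != 1 else k for k, v in sorted(u.normalized().items())]
    return "*".join(parts) if parts else "dimensionless"


def _derive_apply(node: Apply, model, env, time_units, warnings) -> UnitResult:
    op = node.op
    args = [_derive(a, model, env, time_units, warnings) for a in node.args]
    if op == "times":
        out = UnitVector()
        for a in args:
            if a is UNDECLARED:
                return UNDECLARED
            out = out.times(a)
        return out
    if op == "divide":
        if UNDECLARED in args:
            return UNDECLARED
        return args[0].divide(args[1])
    if op in ("plus",) or (op == "minus" and len(args) == 2):
        return _require_identical(args, op, warnings)
    if op == "minus":  # unary
        return args[0]
    if op in ("abs", "floor", "ceiling"):
        return args[0]
    if op in M.RELATIONAL_OPS:
        _require_identical(args, op, warnings)
        return UnitVector()
    if op in M.LOGICAL_OPS:
        return UnitVector()
    if op in ("exp", "ln", "sin", "cos", "tan"):
        a = args[0]
        if a is not UNDECLARED and not a.is_dimensionless():
            warnings.append(f"argument of {op} should be dimensionless")
        return UnitVector()
    if op == "log":
        for a in args:
            if a is not UNDECLARED and not a.is_dimensionless():
                warnings.append("argument of log should be dimensionless")
        return UnitVector()
    if op == "power":
        base, expo_units = args[0], args[1]
        expo_node = node.args[1]
        if expo_units is not UNDECLARED and not expo_units.is_dimensionless():
            warnings.append("exponent of power should be dimensionless")
            return UNDECLARED
        if base is UNDECLARED:
            return UNDECLARED
        if base.is_dimensionless():
            return UnitVector()
        if isinstance(expo_node, Number) and float(expo_node.value).is_integer():
            return base.power(expo_node.value)
        return UNDECLARED
    if op == "root":
        degree_node = node.args[0]
        base = args[1]
        if base is UNDECLARED:
            return UNDECLARED
        if base.is_dimensionless():
            return UnitVector()
        if isinstance(degree_node, Number) and degree_node.value != 0:
            return base.power(1.0 / degree_node.value)
        return UNDECLARED
    return UNDECLARED


# ---------------------------------------------------------------------------
# Document validation
# ---------------------------------------------------------------------------


class _Collector:
    def __init__(self, order: dict[str, int]):
        self.order = order
        self.items: list[tuple[int, Diagnostic]] = []

    def add(self, rule_id: str, path: str, message: str) -> None:
        severity = "warning" if rule_id.startswith("W") else "error"
        pos = self.order.get(path, len(self.order))
        self.items.append((pos, Diagnostic(rule_id, severity, path, message)))

    def sorted(self) -> list[Diagnostic]:
        self.items.sort(key=lambda t: (t[0], t[1].rule_id, t[1].path))
        return [d for _, d in self.items]


def _document_paths(m: Model) -> dict[str, int]:
    """Canonical document-order index for every element path."""
    paths: list[str] = ["model"]
    for f in m.function_definitions:
        paths.append(f"model/listOfFunctionDefinitions/{f.id}")
    for u in m.unit_definitions:
        paths.append(f"model/listOfUnitDefinitions/{u.id}")
    for c in m.compartments:
        paths.append(f"model/listOfCompartments/{c.id}")
    for s in m.species:
        paths.append(f"model/listOfSpecies/{s.id}")
    for p in m.parameters:
        paths.append(f"model/listOfParameters/{p.id}")
    for i, ia in enumerate(m.initial_assignments):
        paths.append(f"model/listOfInitialAssignments/{i}")
    for i, r in enumerate(m.rules):
        paths.append(f"model/listOfRules/{i}")
    for r in m.reactions:
        base = f"model/listOfReactions/{r.id}"
        paths.append(base)
        for i, ref in enumerate(r.reactants):
            paths.append(f"{base}/reactants/{i}")
        for i, ref in enumerate(r.products):
            paths.append(f"{base}/products/{i}")
        paths.append(f"{base}/kineticLaw")
    for i, e in enumerate(m.events):
        paths.append(f"model/listOfEvents/{e.id or i}")
    if m.fbc is not None:
        paths.append("model/fbc")
        for obj in m.fbc.objectives:
            paths.append(f"model/fbc/listOfObjectives/{obj.id}")
        for gp in m.fbc.gene_products:
            paths.append(f"model/fbc/listOfGeneProducts/{gp.id}")
    if m.qual is not None:
        for qs in m.qual.species:
            paths.append(f"model/qual/listOfQualitativeSpecies/{qs.id}")
        for i, tr in enumerate(m.qual.transitions):
            paths.append(f"model/qual/listOfTransitions/{tr.id or i}")
    return {p: i for i, p in enumerate(paths)}


def validate_document(doc: Document) -> list[Diagnostic]:
    """Run the full rule catalog; pure (same document, same findings)."""
    m = doc.model
    if m is None:
        return []
    out = _Collector(_document_paths(m))
    _check_sids(m, out)
    _check_references(m, out)
    _check_rule_targets(m, out)
    _check_missing_attrs(m, out)
    _check_math(m, out)
    _check_unsupported(m, out)
    _check_units(m, out)
    if m.fbc is not None:
        _check_fbc(m, out)
    if m.qual is not None:
        _check_qual(m, out)
    return out.sorted()


def _check_sids(m: Model, out: _Collector) -> None:
    seen: dict[str, str] = {}
    for sid, element in m.sid_elements():
        path = _path_for(m, sid)
        if not is_valid_sid(sid):
            out.add("E1009", path, f"invalid SId syntax {sid!r}")
            continue
        if sid in seen:
            out.add("E1001", path, f"duplicate SId {sid!r} (first at {seen[sid]})")
        else:
            seen[sid] = path


def _path_for(m: Model, sid: str) -> str:
    for c in m.compartments:
        if c.id == sid:
            return f"model/listOfCompartments/{sid}"
    for s in m.species:
        if s.id == sid:
            return f"model/listOfSpecies/{sid}"
    for p in m.parameters:
        if p.id == sid:
            return f"model/listOfParameters/{sid}"
    for r in m.reactions:
        if r.id == sid:
            return f"model/listOfReactions/{sid}"
    if m.qual is not None:
        for qs in m.qual.species:
            if qs.id == sid:
                return f"model/qual/listOfQualitativeSpecies/{sid}"
    if m.fbc is not None:
        for gp in m.fbc.gene_products:
            if gp.id == sid:
                return f"model/fbc/listOfGeneProducts/{sid}"
        for obj in m.fbc.objectives:
            if obj.id == sid:
                return f"model/fbc/listOfObjectives/{sid}"
    return f"model/{sid}"


def _known_sids(m: Model) -> set[str]:
    return {sid for sid, _ in m.sid_elements()}


def _check_references(m: Model, out: _Collector) -> None:
    compartment_ids = {c.id for c in m.compartments}
    species_ids = {s.id for s in m.species}
    variable_ids = (
        compartment_ids | species_ids | {p.id for p in m.parameters}
        | {ref.id for r in m.reactions
           for ref in list(r.reactants) + list(r.products) if ref.id}
    )
    for s in m.species:
        if s.compartment not in compartment_ids:
            out.add("E1002", f"model/listOfSpecies/{s.id}",
                    f"species {s.id!r} references unknown compartment "
                    f"{s.compartment!r}")
    for r in m.reactions:
        base = f"model/listOfReactions/{r.id}"
        for kind, refs in (("reactants", r.reactants), ("products", r.products)):
            for i, ref in enumerate(refs):
                if ref.species not in species_ids:
                    out.add("E1002", f"{base}/{kind}/{i}",
                            f"species reference {ref.species!r} does not resolve")
        for mod in r.modifiers:
            if mod not in species_ids:
                out.add("E1002", base,
                        f"modifier {mod!r} does not resolve to a species")
    for i, rule in enumerate(m.rules):
        if rule.variable not in variable_ids:
            out.add("E1002", f"model/listOfRules/{i}",
                    f"rule variable {rule.variable!r} does not resolve")
    for i, ia in enumerate(m.initial_assignments):
        if ia.symbol not in variable_ids:
            out.add("E1002", f"model/listOfInitialAssignments/{i}",
                    f"initial-assignment symbol {ia.symbol!r} does not resolve")
    for i, e in enumerate(m.events):
        for ea in e.assignments:
            if ea.variable not in variable_ids:
                out.add("E1002", f"model/listOfEvents/{e.id or i}",
                        f"event assignment variable {ea.variable!r} does not "
                        "resolve")
    if m.fbc is not None:
        declared_gp = {gp.id for gp in m.fbc.gene_products}
        reaction_ids = {r.id for r in m.reactions}
        for obj in m.fbc.objectives:
            for rid, _ in obj.terms:
                if rid not in reaction_ids:
                    out.add("E1002", f"model/fbc/listOfObjectives/{obj.id}",
                            f"flux objective references unknown reaction {rid!r}")
        for r in m.reactions:
            if r.gene_association is not None:
                missing = r.gene_association.gene_product_refs() - declared_gp
                for gp in sorted(missing):
                    out.add("E1002", f"model/listOfReactions/{r.id}",
                            f"gene association references undeclared gene "
                            f"product {gp!r}")
    if m.qual is not None:
        q_ids = {qs.id for qs in m.qual.species}
        for i, tr in enumerate(m.qual.transitions):
            path = f"model/qual/listOfTransitions/{tr.id or i}"
            for inp in tr.inputs:
                if inp.qual_species not in q_ids:
                    out.add("E1002", path,
                            f"input references unknown qual species "
                            f"{inp.qual_species!r}")
            for o in tr.outputs:
                if o.qual_species not in q_ids:
                    out.add("E1002", path,
                            f"output references unknown qual species "
                            f"{o.qual_species!r}")


def _is_constant_target(m: Model, sid: str) -> bool:
    for c in m.compartments:
        if c.id == sid:
            return c.constant
    for s in m.species:
        if s.id == sid:
            return s.constant
    for p in m.parameters:
        if p.id == sid:
            return p.constant
    return False


def _check_rule_targets(m: Model, out: _Collector) -> None:
    rule_vars: dict[str, int] = {}
    for i, rule in enumerate(m.rules):
        path = f"model/listOfRules/{i}"
        if rule.variable in rule_vars:
            out.add("E1003", path,
                    f"more than one rule targets {rule.variable!r}")
        rule_vars[rule.variable] = i
        if _is_constant_target(m, rule.variable):
            out.add("E1004", path,
                    f"rule targets constant element {rule.variable!r}")
    ia_syms: set[str] = set()
    for i, ia in enumerate(m.initial_assignments):
        path = f"model/listOfInitialAssignments/{i}"
        if ia.symbol in ia_syms:
            out.add("E1003", path,
                    f"more than one initial assignment targets {ia.symbol!r}")
        ia_syms.add(ia.symbol)
    for i, e in enumerate(m.events):
        for ea in e.assignments:
            if _is_constant_target(m, ea.variable):
                out.add("E1004", f"model/listOfEvents/{e.id or i}",
                        f"event assignment targets constant element "
                        f"{ea.variable!r}")
    # E1005: rate-ruled, non-boundary species that also sits in a reaction
    rate_ruled = {r.variable for r in m.rules if r.kind == "rate"}
    for s in m.species:
        if s.id in rate_ruled and not s.boundary_condition:
            for r in m.reactions:
                participates = any(
                    ref.species == s.id
                    for ref in list(r.reactants) + list(r.products)
                )
                if participates:
                    out.add(
                        "E1005", f"model/listOfSpecies/{s.id}",
                        f"species {s.id!r} has a rate rule but is not a "
                        f"boundary species and participates in reaction "
                        f"{r.id!r}",
                    )
                    break


def _check_missing_attrs(m: Model, out: _Collector) -> None:
    def report(element, path):
        for attr in getattr(element, "missing_attrs", []):
            out.add("E1006", path, f"missing required attribute {attr!r}")

    for c in m.compartments:
        report(c, f"model/listOfCompartments/{c.id}")
    for s in m.species:
        report(s, f"model/listOfSpecies/{s.id}")
    for p in m.parameters:
        report(p, f"model/listOfParameters/{p.id}")
    for r in m.reactions:
        report(r, f"model/listOfReactions/{r.id}")
        for kind, refs in (("reactants", r.reactants), ("products", r.products)):
            for i, ref in enumerate(refs):
                report(ref, f"model/listOfReactions/{r.id}/{kind}/{i}")
    for i, e in enumerate(m.events):
        path = f"model/listOfEvents/{e.id or i}"
        report(e, path)
        report(e.trigger, path)
    if m.qual is not None:
        for qs in m.qual.species:
            report(qs, f"model/qual/listOfQualitativeSpecies/{qs.id}")


def _math_containers(m: Model):
    """Yield (path, node, reaction-scope) for every math container."""
    for i, ia in enumerate(m.initial_assignments):
        yield f"model/listOfInitialAssignments/{i}", ia.math, None
    for i, r in enumerate(m.rules):
        yield f"model/listOfRules/{i}", r.math, None
    for r in m.reactions:
        if r.kinetic_law is not None and r.kinetic_law.math is not None:
            yield f"model/listOfReactions/{r.id}/kineticLaw", \
                r.kinetic_law.math, r.id
    for i, e in enumerate(m.events):
        path = f"model/listOfEvents/{e.id or i}"
        yield path, e.trigger.math, None
        if e.delay is not None:
            yield path, e.delay, None
        for ea in e.assignments:
            yield path, ea.math, None
    if m.qual is not None:
        for i, tr in enumerate(m.qual.transitions):
            for ft in tr.function_terms:
                yield (f"model/qual/listOfTransitions/{tr.id or i}",
                       ft.math, None)


def _check_math(m: Model, out: _Collector) -> None:
    defs = {f.id: f.math for f in m.function_definitions}
    known = _known_sids(m)
    for path, node, scope in _math_containers(m):
        try:
            inlined = inline_function_definitions(node, defs)
        except MathNameError as exc:
            out.add("E1007", path, str(exc))
            continue
        except (MathCycleError, MathStructureError) as exc:
            out.add("E1008", path, str(exc))
            continue
        fs = free_symbols(inlined)
        local_ids = set()
        if scope is not None:
            for r in m.reactions:
                if r.id == scope and r.kinetic_law is not None:
                    local_ids = {lp.id for lp in r.kinetic_law.local_parameters}
        for sid in sorted(fs.names - known - local_ids):
            out.add("E1007", path, f"math references undefined symbol {sid!r}")


def _check_unsupported(m: Model, out: _Collector) -> None:
    for path, message in m.unsupported_constructs:
        out.add("E1008", f"model/{path}", message)


def _check_units(m: Model, out: _Collector) -> None:
    defs = {f.id: f.math for f in m.function_definitions}
    for path, node, scope in _math_containers(m):
        warnings: list[str] = []
        try:
            inlined = inline_function_definitions(node, defs)
        except Exception:
            continue  # already reported by _check_math
        derive_units(inlined, m, scope=scope, warnings=warnings)
        for w in warnings:
            out.add("W2001", path, w)
    compartment_by_id = {c.id: c for c in m.compartments}
    for s in m.species:
        c = compartment_by_id.get(s.compartment)
        uses_concentration = (
            s.initial_concentration is not None
            or not s.has_only_substance_units
        )
        if c is not None and c.size is None and uses_concentration:
            out.add("W2002", f"model/listOfSpecies/{s.id}",
                    f"species {s.id!r} is concentration-based but compartment "
                    f"{c.id!r} has no size")


def _check_fbc(m: Model, out: _Collector) -> None:
    ext = m.fbc
    params = {p.id: p for p in m.parameters}
    for r in m.reactions:
        path = f"model/listOfReactions/{r.id}"
        for which, ref in (("lower", r.lower_flux_bound),
                           ("upper", r.upper_flux_bound)):
            if ref is None:
                if ext.strict:
                    out.add("E3001", path,
                            f"reaction {r.id!r} lacks a {which} flux bound")
                continue
            p = params.get(ref)
            if p is None:
                out.add("E3001", path,
                        f"{which} flux bound {ref!r} does not resolve to a "
                        "parameter")
            elif not p.constant:
                out.add("E3001", path,
                        f"{which} flux bound {ref!r} is not constant")
    active = ext.active_objective
    if active is None or all(obj.id != active for obj in ext.objectives):
        out.add("E3002", "model/fbc", "no active objective")


def _check_qual(m: Model, out: _Collector) -> None:
    qm = m.qual
    max_levels = {qs.id: qs.max_level for qs in qm.species}
    for qs in qm.species:
        if qs.initial_level is not None and qs.initial_level > qs.max_level:
            out.add("E4001", f"model/qual/listOfQualitativeSpecies/{qs.id}",
                    f"initialLevel {qs.initial_level} exceeds maxLevel "
                    f"{qs.max_level}")
    for i, tr in enumerate(qm.transitions):
        path = f"model/qual/listOfTransitions/{tr.id or i}"
        levels = [ft.result_level for ft in tr.function_terms]
        if tr.default_term is not None:
            levels.append(tr.default_term.result_level)
        for o in tr.outputs:
            cap = max_levels.get(o.qual_species)
            if cap is None:
                continue  # E1002 already reported
            for lvl in levels:
                if lvl > cap:
                    out.add("E4002", path,
                            f"result level {lvl} exceeds maxLevel {cap} of "
                            f"output {o.qual_species!r}")
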