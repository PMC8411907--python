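"""Flux Balance Constraints (fbc) package: bounds, objectives, gene
associations, FBA and FVA.

A constraint-based model fixes no kinetics; instead each reaction flux
``v_r`` is bounded (``lb_r <= v_r <= ub_r``, bounds referenced as constant
parameters) and the network is assumed at steady state, ``S v = 0`` over the
non-boundary, non-constant species.  Flux balance analysis (FBA) optimizes a
linear objective ``c . v`` over that polytope; flux variability analysis
(FVA) reports, per reaction, the attainable flux range while holding the
objective within a fraction of its optimum.

Gene-product associations (GPAs) are boolean trees over gene products;
knocking out a set of gene products turns off every reaction whose GPA
evaluates false (bounds clamped to zero).

The LP itself is solved with the HiGHS backend of
:func:`scipy.optimize.linprog`; construction of the program from the
document model is done here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import linprog

from .errors import ModelCompileError, SolverError
from .model import Model

FBC_V2_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version2"

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class GPA:
    """Gene-product association node: exactly one of ref/and_/or_ is set."""

    ref: Optional[str] = None
    and_: Optional[list["GPA"]] = None
    or_: Optional[list["GPA"]] = None

    def __post_init__(self):
        set_fields = sum(x is not None for x in (self.ref, self.and_, self.or_))
        if set_fields != 1:
            raise ModelCompileError("GPA node must be exactly one of ref/and/or")
        for children in (self.and_, self.or_):
            if children is not None and len(children) == 0:
                raise ModelCompileError("GPA and/or node with no children")

    def gene_product_refs(self) -> set[str]:
        if self.ref is not None:
            return {self.ref}
        out: set[str] = set()
        for child in self.and_ or self.or_ or []:
            out |= child.gene_product_refs()
        return out


def gpa_ref(gene_product: str) -> GPA:
    return GPA(ref=gene_product)


def gpa_and(*children: GPA) -> GPA:
    return GPA(and_=list(children))


def gpa_or(*children: GPA) -> GPA:
    return GPA(or_=list(children))


def evaluate_gpa(gpa: GPA, present: Iterable[str]) -> bool:
    """Standard boolean semantics: a leaf is true iff its gene product is
    in ``present``."""
    present = set(present)

    def ev(node: GPA) -> bool:
        if node.ref is not None:
            return node.ref in present
        if node.and_ is not None:
            return all(ev(c) for c in node.and_)
        return any(ev(c) for c in node.or_)

    return ev(gpa)


@dataclass
class GeneProduct:
    id: str
    label: str = ""


@dataclass
class Objective:
    id: str
    type: str  # "maximize" | "minimize"
    terms: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.type not in ("maximize", "minimize"):
            raise ModelCompileError(f"unknown objective type {self.type!r}")


@dataclass
class FbcExtension:
    objectives: list[Objective] = field(default_factory=list)
    active_objective: Optional[str] = None
    gene_products: list[GeneProduct] = field(default_factory=list)
    strict: bool = True


@dataclass
class LinearProgram:
    """S v = 0, lb <= v <= ub, optimize c . v."""

    S: np.ndarray  # species x reactions
    species_ids: list[str]
    reaction_ids: list[str]
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    sense: str  # "max" | "min"


@dataclass
class FbaResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: Optional[float]
    fluxes: dict[str, float]


# ---------------------------------------------------------------------------
# LP construction
# ---------------------------------------------------------------------------


def _bound_value(model: Model, reaction_id: str, param_sid: Optional[str],
                 which: str) -> float:
    if param_sid is None:
        raise ModelCompileError(
            f"E3001: reaction {reaction_id!r} has no {which} flux bound"
        )
    try:
        p = model.parameter_by_id(param_sid)
    except LookupError:
        raise ModelCompileError(
            f"E3001: flux bound parameter {param_sid!r} of reaction "
            f"{reaction_id!r} does not resolve"
        ) from None
    if not p.constant:
        raise ModelCompileError(
            f"E3001: flux bound parameter {param_sid!r} is not constant"
        )
    if p.value is None:
        raise ModelCompileError(
            f"E3001: flux bound parameter {param_sid!r} has no value"
        )
    return p.value


def build_lp(model: Model) -> LinearProgram:
    """Compile the fbc extension of ``model`` into a linear program.

    Mass-balance rows cover species that are neither boundary-condition nor
    constant; bounds come from the referenced constant parameters; the
    objective vector from the active objective's flux terms.
    """
    ext: FbcExtension | None = model.fbc
    if ext is None:
        raise ModelCompileError("model has no fbc extension")
    active = None
    for obj in ext.objectives:
        if obj.id == ext.active_objective:
            active = obj
    if active is None:
        raise ModelCompileError("E3002: no active objective")

    balanced = [
        s for s in model.species if not s.boundary_condition and not s.constant
    ]
    species_ids = [s.id for s in balanced]
    row = {sid: i for i, sid in enumerate(species_ids)}
    reaction_ids = [r.id for r in model.reactions]
    col = {rid: j for j, rid in enumerate(reaction_ids)}

    S = np.zeros((len(species_ids), len(reaction_ids)))
    lb = np.empty(len(reaction_ids))
    ub = np.empty(len(reaction_ids))
    for j, r in enumerate(model.reactions):
        for ref in r.reactants:
            if ref.species in row:
                S[row[ref.species], j] -= ref.stoichiometry
        for ref in r.products:
            if ref.species in row:
                S[row[ref.species], j] += ref.stoichiometry
        lb[j] = _bound_value(model, r.id, r.lower_flux_bound, "lower")
        ub[j] = _bound_value(model, r.id, r.upper_flux_bound, "upper")

    c = np.zeros(len(reaction_ids))
    for rid, coeff in active.terms:
        if rid not in col:
            raise ModelCompileError(
                f"objective term references unknown reaction {rid!r}"
            )
        c[col[rid]] += coeff
    sense = "max" if active.type == "maximize" else "min"
    return LinearProgram(S, species_ids, reaction_ids, lb, ub, c, sense)


# ---------------------------------------------------------------------------
# Solving
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _apply_knockouts(model: Model, lp: LinearProgram,
                     knockouts: Iterable[str]) -> LinearProgram:
    ext: FbcExtension = model.fbc
    knocked = set(knockouts)
    declared = {gp.id for gp in ext.gene_products}
    unknown = knocked - declared
    if unknown:
        raise ModelCompileError(
            f"knockout of undeclared gene product(s): {sorted(unknown)}"
        )
    present = declared - knocked
    lb = lp.lb.copy()
    ub = lp.ub.copy()
    for j, r in enumerate(model.reactions):
        if r.gene_association is not None and not evaluate_gpa(
            r.gene_association, present
        ):
            lb[j] = 0.0
            ub[j] = 0.0
    return LinearProgram(lp.S, lp.species_ids, lp.reaction_ids, lb, ub,
                         lp.c, lp.sense)


def _solve(lp: LinearProgram, c: np.ndarray, sense: str,
           extra_A_ub=None, extra_b_ub=None) -> tuple[str, float | None, np.ndarray | None]:
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=lp.S if lp.S.size else None,
        b_eq=np.zeros(lp.S.shape[0]) if lp.S.size else None,
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        bounds=list(zip(lp.lb, lp.ub)),
        method="highs",
    )
    status = _STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failed: {res.message}")
    if status != "optimal":
        return status, None, None
    return status, sign * res.fun, res.x


def solve_fba(model: Model, knockouts: Optional[Iterable[str]] = None) -> FbaResult:
    """Flux balance analysis, optionally under gene-product knockouts.

    Reactions whose GPA evaluates false under the knockout get both bounds
    clamped to zero before solving; reactions without a GPA are unaffected.
    """
    lp = build_lp(model)
    if knockouts:
        lp = _apply_knockouts(model, lp, knockouts)
    status, value, x = _solve(lp, lp.c, lp.sense)
    fluxes = (
        {rid: float(v) for rid, v in zip(lp.reaction_ids, x)} if x is not None else {}
    )
    return FbaResult(status=status, objective_value=value, fluxes=fluxes)


def flux_variability(model: Model, fraction_of_optimum: float = 1.0,
                     knockouts: Optional[Iterable[str]] = None
                     ) -> dict[str, dict[str, float]]:
    """Per-reaction flux ranges with the objective held at or above
    ``fraction_of_optimum`` times its optimal value (for maximization;
    at or below for minimization)."""
    if not (0.0 < fraction_of_optimum <= 1.0):
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    lp = build_lp(model)
    if knockouts:
        lp = _apply_knockouts(model, lp, knockouts)
    status, opt, _ = _solve(lp, lp.c, lp.sense)
    if status != "optimal":
        raise SolverError(f"FBA not optimal (status {status}); FVA undefined")
    # objective constraint as an inequality row
    if lp.sense == "max":
        A_ub = -lp.c.reshape(1, -1)
        b_ub = np.array([-fraction_of_optimum * opt])
    else:
        A_ub = lp.c.reshape(1, -1)
        b_ub = np.array([fraction_of_optimum * opt])
    out: dict[str, dict[str, float]] = {}
    n = len(lp.reaction_ids)
    for j, rid in enumerate(lp.reaction_ids):
        e = np.zeros(n)
        e[j] = 1.0
        s_min, v_min, _ = _solve(lp, e, "min", A_ub, b_ub)
        s_max, v_max, _ = _solve(lp, e, "max", A_ub, b_ub)
        if s_min != "optimal" or s_max != "optimal":
            raise SolverError(f"FVA subproblem for {rid!r} not optimal")
        out[rid] = {"min": float(v_min), "max": float(v_max)}
    return out


def fluxes_to_tsv(model: Model, result: FbaResult,
                  fva: Optional[dict[str, dict[str, float]]] = None) -> str:
    """Serialize flux results; columns reaction_id, flux, lower_bound,
    upper_bound (+ min/max when FVA ranges are given)."""
    lp = build_lp(model)
    header = ["reaction_id", "flux", "lower_bound", "upper_bound"]
    if fva is not None:
        header += ["min", "max"]
    lines = ["\t".join(header)]
    for j, rid in enumerate(lp.reaction_ids):
        rowvals = [rid, repr(result.fluxes.get(rid, float("nan"))),
                   repr(float(lp.lb[j])), repr(float(lp.ub[j]))]
        if fva is not None:
            rowvals += [repr(fva[rid]["min"]), repr(fva[rid]["max"])]
        lines.append("\t".join(rowvals))
    return "\n".join(lines) + "\n"
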