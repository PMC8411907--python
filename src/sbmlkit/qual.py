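"""Qualitative Models (qual) package: discrete-level species, logical
transitions, state-transition graphs and attractors.

A qualitative species holds a level in ``0..maxLevel``; a transition lists
input species, output species, and an ordered list of function terms whose
boolean math (over current input levels) selects the first applicable
result level, falling back to a default term.  Dynamics come in two
schemes:

``synchronous``
    every state has exactly one successor, with all species jumping to
    their target level at once;
``asynchronous``
    each species whose target differs from its current level contributes
    one successor in which only that species moves by one unit toward the
    target (the usual unitary-update convention for multivalued logical
    models).

The state-transition graph is enumerated explicitly over the full state
space; attractors are its terminal strongly connected components (computed
with networkx), fixed points being the singleton ones.

Input ``sign``/``threshold`` attributes are carried as data but do not
affect dynamics — the function terms are authoritative.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx

from .errors import CapacityError, MathTypeError, ModelCompileError, SbmlFormatError
from .mathml import EvalEnv, MathNode, evaluate
from .model import Model

QUAL_V1_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"

INPUT_SIGNS = frozenset({"positive", "negative", "dual", "unknown"})

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class QualSpecies:
    id: str
    compartment: Optional[str] = None
    max_level: int = 1
    initial_level: Optional[int] = None
    constant: bool = False
    missing_attrs: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.max_level < 1:
            raise SbmlFormatError(
                f"qual species {self.id!r}: maxLevel must be >= 1"
            )


@dataclass
class QualInput:
    qual_species: str
    sign: str = "unknown"
    threshold: Optional[int] = None
    transition_effect: str = "none"

    def __post_init__(self):
        if self.sign not in INPUT_SIGNS:
            raise SbmlFormatError(f"unknown input sign {self.sign!r}")


@dataclass
class QualOutput:
    qual_species: str
    transition_effect: str = "assignmentLevel"


@dataclass
class FunctionTerm:
    result_level: int
    math: MathNode


@dataclass
class DefaultTerm:
    result_level: int


@dataclass
class QualTransition:
    id: Optional[str] = None
    inputs: list[QualInput] = field(default_factory=list)
    outputs: list[QualOutput] = field(default_factory=list)
    function_terms: list[FunctionTerm] = field(default_factory=list)
    default_term: Optional[DefaultTerm] = None


@dataclass
class QualModel:
    species: list[QualSpecies] = field(default_factory=list)
    transitions: list[QualTransition] = field(default_factory=list)

    def species_by_id(self, sid: str) -> QualSpecies:
        for s in self.species:
            if s.id == sid:
                return s
        raise SbmlFormatError(f"unknown qual species {sid!r}")


@dataclass
class StateTransitionGraph:
    """Explicit STG; states are tuples of levels in ``species_ids`` order."""

    species_ids: list[str]
    nodes: list[tuple[int, ...]]
    edges: list[tuple[tuple[int, ...], tuple[int, ...]]]
    scheme: str


@dataclass
class Attractor:
    states: tuple[tuple[int, ...], ...]
    fixed_point: bool


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def _transition_for(qm: QualModel, species: str) -> Optional[QualTransition]:
    found = None
    for tr in qm.transitions:
        if any(out.qual_species == species for out in tr.outputs):
            if found is not None:
                raise ModelCompileError(
                    f"qual species {species!r} is the output of more than one "
                    "transition (ambiguous regulation)"
                )
            found = tr
    return found


def target_level(model: Model, state: Mapping[str, int], species: str) -> int:
    """Level the regulation of ``species`` aims at in ``state``.

    Function terms are tried in document order with input levels bound as
    integers; the first term whose boolean math is true wins, otherwise the
    default term applies.  Species without a transition, and constant
    species, keep their current level.
    """
    qm: QualModel = model.qual
    if qm is None:
        raise ModelCompileError("model has no qual extension")
    sp = qm.species_by_id(species)
    current = int(state[species])
    if sp.constant:
        return current
    tr = _transition_for(qm, species)
    if tr is None:
        return current
    env = EvalEnv(bindings={sid: float(v) for sid, v in state.items()})
    for term in tr.function_terms:
        val = evaluate(term.math, env)
        if not isinstance(val, bool):
            raise MathTypeError(
                f"function term of {species!r} is not boolean-valued"
            )
        if val:
            return term.result_level
    if tr.default_term is None:
        raise ModelCompileError(
            f"transition for {species!r} has no default term and no true "
            "function term"
        )
    return tr.default_term.result_level


def _step_toward(current: int, target: int) -> int:
    if target > current:
        return current + 1
    if target < current:
        return current - 1
    return current


def build_stg(model: Model, scheme: str, cap: int = 2 ** 20) -> StateTransitionGraph:
    """Enumerate the full discrete state space and its transition relation.

    The relation is total: states with no change get a self-loop.  The
    ``cap`` guards against accidental state-space explosions.
    """
    if scheme not in ("synchronous", "asynchronous"):
        raise ValueError(f"unknown update scheme {scheme!r}")
    qm: QualModel = model.qual
    if qm is None:
        raise ModelCompileError("model has no qual extension")
    size = 1
    for sp in qm.species:
        if not sp.constant:
            size *= sp.max_level + 1
    if size > cap:
        raise CapacityError(
            f"state space has {size} states, exceeding the cap of {cap}"
        )
    ids = [sp.id for sp in qm.species]
    ranges = []
    for sp in qm.species:
        if sp.constant:
            lvl = sp.initial_level if sp.initial_level is not None else 0
            ranges.append((lvl,))
        else:
            ranges.append(tuple(range(sp.max_level + 1)))
    nodes = [tuple(s) for s in itertools.product(*ranges)]

    edges: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    for node in nodes:
        state = dict(zip(ids, node))
        targets = [target_level(model, state, sid) for sid in ids]
        if scheme == "synchronous":
            succ = tuple(targets)
            edges.append((node, succ))
        else:
            changed = False
            for i, sid in enumerate(ids):
                if targets[i] != node[i]:
                    succ = list(node)
                    succ[i] = _step_toward(node[i], targets[i])
                    edges.append((node, tuple(succ)))
                    changed = True
            if not changed:
                edges.append((node, node))
    return StateTransitionGraph(ids, nodes, edges, scheme)


def find_attractors(stg: StateTransitionGraph) -> list[Attractor]:
    """Terminal strongly connected components of the STG.

    Output order is deterministic: attractors sorted by their
    lexicographically smallest member state; member states sorted too.
    """
    g = nx.DiGraph()
    g.add_nodes_from(stg.nodes)
    g.add_edges_from(stg.edges)
    cond = nx.condensation(g)
    attractors = []
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:
            members = tuple(sorted(cond.nodes[comp_id]["members"]))
            fixed = len(members) == 1
            attractors.append(Attractor(states=members, fixed_point=fixed))
    attractors.sort(key=lambda a: a.states[0])
    return attractors


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _state_label(stg: StateTransitionGraph, state: tuple[int, ...]) -> str:
    return "_".join(f"{sid}{lvl}" for sid, lvl in zip(stg.species_ids, state))


def stg_to_dot(stg: StateTransitionGraph) -> str:
    """One node per state, labeled by its level vector (e.g. ``A1_B0``)."""
    lines = ["digraph stg {"]
    for node in stg.nodes:
        lines.append(f'  "{_state_label(stg, node)}";')
    for src, dst in stg.edges:
        lines.append(
            f'  "{_state_label(stg, src)}" -> "{_state_label(stg, dst)}";'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def stg_to_tsv(stg: StateTransitionGraph) -> str:
    lines = ["source\ttarget"]
    for src, dst in stg.edges:
        lines.append(f"{_state_label(stg, src)}\t{_state_label(stg, dst)}")
    return "\n".join(lines) + "\n"


def attractors_to_json(stg: StateTransitionGraph,
                       attractors: list[Attractor]) -> str:
    payload = [
        {
            "fixed_point": a.fixed_point,
            "states": [
                dict(zip(stg.species_ids, state)) for state in a.states
            ],
        }
        for a in attractors
    ]
    return json.dumps(payload, indent=2) + "\n"
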